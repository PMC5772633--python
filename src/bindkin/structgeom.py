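"""Structure geometry: sidechain dihedrals, superposition, distances.

Conventions
-----------
Dihedrals use the signed IUPAC convention,
``atan2((n1 × n2)·b̂2, n1·n2)`` with ``b1 = p2−p1``, ``b2 = p3−p2``,
``b3 = p4−p3``, ``n1 = b1×b2``, ``n2 = b2×b3``; results lie in (−180°, 180°].
χ1 is N–CA–CB–CG, χ2 is CA–CB–CG–CD1 (phenylalanine/tyrosine-type
sidechains).  Superposition is least-squares rigid (Kabsch: centroid shift +
SVD rotation with reflection correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .featurize import Topology, Trajectory

__all__ = [
    "StructureModel",
    "RotamerObservation",
    "dihedral",
    "measure_chi",
    "kabsch_superpose",
    "atom_distance",
    "circular_distance",
    "rotamer_outlier",
    "representative_pose",
]


@dataclass
class StructureModel:
    """A topology with a single coordinate frame (Å)."""

    topology: Topology
    coords: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    def atom_coord(self, res_seq: int, atom_name: str, chain_id: str | None = None):
        return self.coords[self.topology.atom_index(res_seq, atom_name, chain_id)]


@dataclass
class RotamerObservation:
    structure_id: str
    residue_id: int
    chi1: float | None
    chi2: float | None

    def __post_init__(self):
        for angle in (self.chi1, self.chi2):
            if angle is not None and not (-180.0 < angle <= 180.0):
                raise ValueError("chi angles must lie in (-180, 180]")


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, range (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-9:
        raise ValueError("degenerate dihedral: coincident consecutive points")
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-9:
        raise ValueError("degenerate dihedral: collinear points")
    b2_hat = b2 / np.linalg.norm(b2)
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2_hat), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def measure_chi(structure: StructureModel, res_seq: int, chain_id: str | None = None) -> RotamerObservation:
    """Measure χ1 (and χ2 when CD1 exists) for a Phe/Tyr-type residue.

    Missing atoms yield ``None`` for the affected angle rather than an
    exception, so a survey over many structures can proceed.
    """
    def coord(name):
        try:
            return structure.atom_coord(res_seq, name, chain_id)
        except KeyError:
            return None

    n, ca, cb, cg, cd1 = (coord(x) for x in ("N", "CA", "CB", "CG", "CD1"))
    chi1 = chi2 = None
    if all(p is not None for p in (n, ca, cb, cg)):
        chi1 = dihedral(n, ca, cb, cg)
    else:
        warnings.warn(f"residue {res_seq}: atoms missing for chi1", stacklevel=2)
    if all(p is not None for p in (ca, cb, cg, cd1)):
        chi2 = dihedral(ca, cb, cg, cd1)
    else:
        warnings.warn(f"residue {res_seq}: atoms missing for chi2", stacklevel=2)
    return RotamerObservation(structure.source_id, res_seq, chi1, chi2)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray, pairing=None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``pairing`` is an optional sequence of (mobile_idx, reference_idx) pairs;
    by default atoms pair by position.  Returns ``(rotation, translation,
    rmsd)`` such that ``mobile @ rotation.T + translation ≈ reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pairing is not None:
        pairing = np.asarray(pairing, dtype=int)
        m, r = mobile[pairing[:, 0]], reference[pairing[:, 1]]
    else:
        if mobile.shape != reference.shape:
            raise ValueError("shape mismatch and no pairing given")
        m, r = mobile, reference
    if len(m) < 3:
        raise ValueError("need at least 3 paired atoms")
    if np.linalg.matrix_rank(m - m.mean(0), tol=1e-9) < 2:
        raise ValueError("paired atoms are collinear")
    mc, rc = m.mean(0), r.mean(0)
    h = (m - mc).T @ (r - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = m @ rot.T + trans
    rmsd = float(np.sqrt(((moved - r) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def atom_distance(structure: StructureModel, atom_a, atom_b) -> float:
    """Euclidean distance (Å) between two atoms, each given as
    ``(res_seq, atom_name)`` or a global atom index."""
    def resolve(sel):
        if np.isscalar(sel):
            return structure.coords[int(sel)]
        return structure.atom_coord(*sel)

    return float(np.linalg.norm(resolve(atom_a) - resolve(atom_b)))


def circular_distance(a: float, b: float) -> float:
    """Shortest angular separation in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def rotamer_outlier(observation: RotamerObservation, reference_set, threshold: float = 30.0):
    """Flag an observation whose χ1 lies beyond ``threshold`` degrees
    (circular) from every reference observation.

    Returns ``(is_outlier, nearest_reference, min_chi1_distance)``.
    """
    refs = [r for r in reference_set if r.chi1 is not None]
    if not refs or observation.chi1 is None:
        raise ValueError("need chi1 on the observation and a non-empty reference set")
    dists = [circular_distance(observation.chi1, r.chi1) for r in refs]
    i = int(np.argmin(dists))
    return dists[i] > threshold, refs[i], float(dists[i])


def representative_pose(
    frames: Trajectory,
    reference: StructureModel,
    pocket_selection,
    align_selection=None,
) -> tuple[int, float]:
    """Frame whose pocket atoms best match the reference after superposition.

    ``pocket_selection``/``align_selection`` are (mobile_idx, reference_idx)
    pairings of atom indices; alignment defaults to the pocket pairing.
    Frames are first superposed on the alignment selection (typically Cα) and
    the RMSD of the pocket atoms is then evaluated; the argmin frame index is
    returned (ties → lowest index) together with its pocket RMSD.
    """
    if frames.n_frames == 0:
        raise ValueError("empty frame set")
    pocket = np.asarray(pocket_selection, dtype=int)
    align = pocket if align_selection is None else np.asarray(align_selection, dtype=int)
    best = (np.inf, -1)
    for f in range(frames.n_frames):
        xyz = frames.coordinates[f]
        rot, trans, _ = kabsch_superpose(
            xyz[align[:, 0]], reference.coords[align[:, 1]]
        )
        moved = xyz[pocket[:, 0]] @ rot.T + trans
        rmsd = float(np.sqrt(((moved - reference.coords[pocket[:, 1]]) ** 2).sum(1).mean()))
        if rmsd < best[0] - 1e-12:
            best = (rmsd, f)
    return best[1], best[0]
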