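"""Protein–ligand contact featurization.

Two binary representations of a trajectory are produced:

* a per-frame residue **contact map**: residue ``r`` is in contact at frame
  ``f`` iff any heavy atom of ``r`` lies strictly closer than ``cutoff_contact``
  (default 5 Å) to any ligand *feature atom* (ligand O, N, and C atoms that
  carry no bonded hydrogen);
* a per-frame **bulk flag**: 1 iff any ligand feature atom is strictly closer
  than ``cutoff_bulk`` (default 10 Å) to any protein Cα atom.  Frames with
  flag 0 have the ligand in bulk solvent.

Distances are plain Euclidean (no periodic wrapping): the analysis assumes the
ligand is kept near the receptor by a flat-bottom restraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "FeatureTrack",
    "read_structure",
    "infer_bonds",
    "ligand_feature_atoms",
    "contact_map",
    "bulk_flag",
    "featurize_trajectory",
    "read_xyz",
    "write_xyz",
]

# single-bond covalent radii (Å), Cordero et al. values rounded
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03,
    "MG": 1.41, "CA": 1.76, "ZN": 1.22, "FE": 1.32,
}
_BOND_TOLERANCE = 1.2


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass
class Topology:
    """Atom/residue metadata for a structure or trajectory.

    Residues are indexed densely from 0 in file order (``res_index``) while
    the original PDB residue numbers are kept in ``res_seq``.
    """

    name: np.ndarray          # str, per atom
    element: np.ndarray       # str, upper-case
    res_index: np.ndarray     # int, dense 0-based
    res_seq: np.ndarray       # int, original PDB numbering
    res_name: np.ndarray      # str
    chain_id: np.ndarray      # str
    ligand_mask: np.ndarray = field(default=None)  # bool, per atom

    def __post_init__(self):
        n = len(self.name)
        for attr in ("element", "res_index", "res_seq", "res_name", "chain_id"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr!r} has wrong length")
        if self.ligand_mask is None:
            self.ligand_mask = np.zeros(n, dtype=bool)
        self.ligand_mask = np.asarray(self.ligand_mask, dtype=bool)
        if self.ligand_mask.shape != (n,):
            raise ValueError("ligand_mask has wrong shape")
        ri = np.asarray(self.res_index)
        if n:
            uniq = np.unique(ri)
            if uniq[0] != 0 or not np.array_equal(uniq, np.arange(len(uniq))):
                raise ValueError("res_index must be dense from 0")

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def n_residues(self) -> int:
        return int(self.res_index.max()) + 1 if self.n_atoms else 0

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.ligand_mask

    def set_ligand_by_resname(self, resname: str) -> None:
        mask = self.res_name == resname
        if not mask.any():
            raise ValueError(f"no atoms with residue name {resname!r}")
        self.ligand_mask = mask

    def atom_index(self, res_seq: int, atom_name: str, chain_id: str | None = None) -> int:
        sel = (self.res_seq == res_seq) & (self.name == atom_name)
        if chain_id is not None:
            sel &= self.chain_id == chain_id
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            raise KeyError(f"atom {atom_name!r} in residue {res_seq} not found")
        return int(idx[0])


@dataclass
class Trajectory:
    """Coordinates (frames × atoms × 3, Å) bound to a :class:`Topology`."""

    topology: Topology
    coordinates: np.ndarray
    frame_interval: float = 1.0  # physical time per saved frame (caller's unit)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[None]
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate/topology atom count mismatch")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class FeatureTrack:
    """Binary contact matrix plus bulk flag for one trajectory."""

    contact_matrix: np.ndarray  # frames × residues, {0,1}
    bulk_flag: np.ndarray       # frames, {0,1}; 0 = ligand in bulk
    cutoff_contact: float = 5.0
    cutoff_bulk: float = 10.0

    def __post_init__(self):
        self.contact_matrix = np.asarray(self.contact_matrix, dtype=np.uint8)
        self.bulk_flag = np.asarray(self.bulk_flag, dtype=np.uint8)
        if self.contact_matrix.ndim != 2:
            raise ValueError("contact_matrix must be 2-D")
        if self.bulk_flag.shape != (self.contact_matrix.shape[0],):
            raise ValueError("bulk_flag length must match frame count")
        for arr in (self.contact_matrix, self.bulk_flag):
            if arr.size and not np.isin(arr, (0, 1)).all():
                raise ValueError("feature entries must be binary")
        if not self.cutoff_contact < self.cutoff_bulk:
            raise ValueError("cutoff_contact must be smaller than cutoff_bulk")

    @property
    def n_frames(self) -> int:
        return self.contact_matrix.shape[0]


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in COVALENT_RADII and stripped[:2].isalpha():
        # two-letter elements only when the PDB name starts in column 13
        return stripped[:2].upper()
    return stripped[0].upper()


def read_structure(path, ligand_resname: str | None = None):
    """Read a PDB file into a :class:`Topology` and one coordinate frame.

    Alternate locations are resolved per (chain, residue, atom name) group by
    keeping the highest-occupancy altloc; occupancy ties keep the
    alphabetically first altloc id ('A' before 'B').

    Returns ``(topology, coords)`` with coords shaped (n_atoms, 3) in Å.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb_file = PDBFile.read(str(path))
        atoms = pdb_file.get_structure(
            model=1, altloc="all", extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:  # noqa: BLE001 - wrap into a descriptive error
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise PDBParseError(f"no ATOM/HETATM coordinates found in {path}")
    if not np.isfinite(atoms.coord).all():
        raise PDBParseError(f"non-finite coordinates in {path}")

    altloc = atoms.get_annotation("altloc_id") if "altloc_id" in atoms.get_annotation_categories() else np.array([""] * atoms.array_length())
    occupancy = atoms.occupancy

    keep = np.ones(atoms.array_length(), dtype=bool)
    keys = {}
    for i in range(atoms.array_length()):
        key = (atoms.chain_id[i], atoms.res_id[i], atoms.ins_code[i], atoms.atom_name[i])
        keys.setdefault(key, []).append(i)
    for idx in keys.values():
        if len(idx) == 1:
            continue
        # altloc group: keep highest occupancy, ties -> smallest altloc id
        best = min(idx, key=lambda i: (-occupancy[i], altloc[i]))
        for i in idx:
            keep[i] = i == best
    atoms = atoms[keep]

    serial = atoms.get_annotation("atom_id")
    if len(np.unique(serial)) != len(serial):
        raise PDBParseError(f"duplicate atom serial numbers in {path}")

    element = np.array([e.upper() for e in atoms.element])
    missing = element == ""
    if missing.any():
        warnings.warn(
            "PDB lacks element columns for some atoms; inferring from atom names",
            stacklevel=2,
        )
        element[missing] = [_element_from_name(n) for n in atoms.atom_name[missing]]

    # dense residue index in file order
    res_key = np.array(
        [f"{c}|{r}|{i}" for c, r, i in zip(atoms.chain_id, atoms.res_id, atoms.ins_code)]
    )
    _, first_pos, inverse = np.unique(res_key, return_index=True, return_inverse=True)
    order = np.argsort(first_pos)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    res_index = rank[inverse]

    top = Topology(
        name=np.array(atoms.atom_name),
        element=element,
        res_index=res_index,
        res_seq=np.array(atoms.res_id),
        res_name=np.array(atoms.res_name),
        chain_id=np.array(atoms.chain_id),
    )
    if ligand_resname is not None:
        top.set_ligand_by_resname(ligand_resname)
    return top, np.asarray(atoms.coord, dtype=float)


def infer_bonds(topology: Topology, coords: np.ndarray, subset: np.ndarray | None = None):
    """Distance-based bond inference: bonded iff d < 1.2 × (r_i + r_j).

    Returns a list of (i, j) index pairs (global atom indices).  Intended for
    small selections (ligands); cost is quadratic in the subset size.
    """
    idx = np.arange(topology.n_atoms) if subset is None else np.asarray(subset)
    xyz = coords[idx]
    radii = np.array([COVALENT_RADII.get(e, 0.77) for e in topology.element[idx]])
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    limit = _BOND_TOLERANCE * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero((dist < limit) & (dist > 1e-6))
    return [(int(idx[i]), int(idx[j])) for i, j in zip(ii, jj) if i < j]


def ligand_feature_atoms(topology: Topology, coords: np.ndarray) -> np.ndarray:
    """Ligand atoms used for featurization.

    All ligand oxygens and nitrogens, plus ligand carbons without a bonded
    hydrogen (bonds inferred from the given coordinates when no bond table is
    available).
    """
    lig = np.flatnonzero(topology.ligand_mask)
    if len(lig) == 0:
        raise ValueError("topology has an empty ligand selection")
    element = topology.element
    keep = [i for i in lig if element[i] in ("N", "O")]
    carbons = [i for i in lig if element[i] == "C"]
    if carbons:
        bonds = infer_bonds(topology, coords, subset=lig)
        h_partners: dict[int, bool] = {i: False for i in carbons}
        for i, j in bonds:
            if i in h_partners and element[j] == "H":
                h_partners[i] = True
            if j in h_partners and element[i] == "H":
                h_partners[j] = True
        keep.extend(i for i in carbons if not h_partners[i])
    if not keep:
        raise ValueError("no usable ligand feature atoms (O, N, or H-free C)")
    return np.array(sorted(keep), dtype=int)


def _residue_min_distances(frame, res_atoms_sorted, res_starts, lig_xyz):
    """Min distance from each residue's atom block to any ligand atom."""
    from scipy.spatial.distance import cdist

    d = cdist(frame[res_atoms_sorted], lig_xyz).min(axis=1)
    return np.minimum.reduceat(d, res_starts)


def _protein_residue_blocks(topology: Topology):
    """Heavy protein atoms grouped contiguously by residue."""
    heavy = topology.protein_mask & (topology.element != "H")
    atom_idx = np.flatnonzero(heavy)
    if len(atom_idx) == 0:
        raise ValueError("no protein heavy atoms in topology")
    res_of = topology.res_index[atom_idx]
    order = np.argsort(res_of, kind="stable")
    atom_idx = atom_idx[order]
    res_of = res_of[order]
    res_ids, starts = np.unique(res_of, return_index=True)
    return atom_idx, starts, res_ids


def contact_map(
    traj: Trajectory,
    feature_atoms: np.ndarray | None = None,
    cutoff: float = 5.0,
):
    """Per-frame binary residue contacts (strict ``< cutoff`` rule).

    Returns ``(matrix, residue_ids)`` where matrix is frames × n_protein_residues
    and ``residue_ids`` maps columns to dense residue indices.
    """
    top = traj.topology
    if feature_atoms is None:
        feature_atoms = ligand_feature_atoms(top, traj.coordinates[0])
    atom_idx, starts, res_ids = _protein_residue_blocks(top)
    out = np.empty((traj.n_frames, len(res_ids)), dtype=np.uint8)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        mind = _residue_min_distances(frame, atom_idx, starts, frame[feature_atoms])
        out[f] = mind < cutoff
    return out, res_ids


def bulk_flag(
    traj: Trajectory,
    feature_atoms: np.ndarray | None = None,
    cutoff: float = 10.0,
) -> np.ndarray:
    """1 iff any ligand feature atom is < cutoff from any protein Cα."""
    from scipy.spatial.distance import cdist

    top = traj.topology
    ca = np.flatnonzero(top.protein_mask & (top.name == "CA"))
    if len(ca) == 0:
        raise ValueError("protein has no CA atoms")
    if traj.n_frames == 0:
        return np.zeros(0, dtype=np.uint8)
    if feature_atoms is None:
        feature_atoms = ligand_feature_atoms(top, traj.coordinates[0])
    flags = np.empty(traj.n_frames, dtype=np.uint8)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        flags[f] = cdist(frame[feature_atoms], frame[ca]).min() < cutoff
    return flags


def featurize_trajectory(
    traj: Trajectory,
    ligand_resname: str | None = None,
    cutoff_contact: float = 5.0,
    cutoff_bulk: float = 10.0,
) -> FeatureTrack:
    """Convenience wrapper: feature atoms + contact map + bulk flag."""
    if ligand_resname is not None:
        traj.topology.set_ligand_by_resname(ligand_resname)
    feats = ligand_feature_atoms(traj.topology, traj.coordinates[0])
    matrix, _ = contact_map(traj, feats, cutoff_contact)
    flags = bulk_flag(traj, feats, cutoff_bulk)
    return FeatureTrack(matrix, flags, cutoff_contact, cutoff_bulk)


def write_xyz(path, traj: Trajectory, comment: str = "") -> None:
    """Write a multi-frame plain-text XYZ file (element x y z, Å)."""
    el = traj.topology.element
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.topology.n_atoms}\n{comment} frame {f}\n")
            for e, (x, y, z) in zip(el, traj.coordinates[f]):
                fh.write(f"{e or 'X'} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Read a multi-frame XYZ file; returns (elements, coords frames×atoms×3)."""
    frames = []
    elements = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        n = int(lines[pos].strip())
        block = lines[pos + 2 : pos + 2 + n]
        parts = [ln.split() for ln in block]
        if elements is None:
            elements = [p[0] for p in parts]
        frames.append([[float(p[1]), float(p[2]), float(p[3])] for p in parts])
        pos += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return elements, np.asarray(frames)
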