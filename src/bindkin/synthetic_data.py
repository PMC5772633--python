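"""Ground-truth generators for testing the binding-analysis pipeline.

The study conditions emulated here are those of a small-molecule ligand
diffusing around a membrane receptor under a flat-bottom cuboid restraint:
a bulk state exchanging quickly with an extracellular-vestibule state, a slow
rate-limiting entry into the bound basin, an alternative route through an
intermediate pose, and one off-pathway pose that exchanges only with bound.

The default discrete chain satisfies detailed balance by construction and its
forward rates are set so that roughly 30% of binding events pass through the
intermediate and the bulk→bound mean first passage time is 85 steps; with the
default step length of 0.0824 μs that is 7.0 μs, matching the conditions the
analysis is meant to operate under.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .featurize import FeatureTrack, Topology, Trajectory
from .structgeom import StructureModel

__all__ = [
    "GroundTruthChain",
    "ToyBindingParams",
    "AssayTruth",
    "MfptResult",
    "default_chain",
    "sample_discrete_trajectories",
    "analytic_mfpt",
    "simulate_toy_binding",
    "make_phe_fixture",
    "generate_dose_response",
    "default_contact_templates",
    "embed_contact_features",
]

R_KCAL = 1.98720e-3  # kcal/(mol K)

DEFAULT_STATE_LABELS = ("bulk", "vestibule", "intermediate", "bound", "offpath")


@dataclass
class GroundTruthChain:
    """A known discrete Markov chain used as the truth for the pipeline."""

    transition_matrix: np.ndarray
    state_labels: tuple = DEFAULT_STATE_LABELS
    lag_time: float = 0.0824  # μs per step

    def __post_init__(self):
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if (t < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if len(self.state_labels) != t.shape[0]:
            raise ValueError("state_labels length must match matrix size")
        if self.lag_time <= 0:
            raise ValueError("lag_time must be positive")
        n_comp, _ = connected_components(csr_matrix(t > 0), connection="strong")
        self._irreducible = n_comp == 1
        self.transition_matrix = t

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def state_index(self, state) -> int:
        if isinstance(state, str):
            return self.state_labels.index(state)
        return int(state)

    def stationary_distribution(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def default_chain(lag_time: float = 0.0824) -> GroundTruthChain:
    """Default 5-state chain (bulk, vestibule, intermediate, bound, offpath).

    Reversible w.r.t. π ∝ (0.9, 1, 1, 10, 5); the off-pathway state exchanges
    only with bound.  Bulk→bound MFPT is 85 steps and ≈30% of binding events
    route through the intermediate.
    """
    t = np.array(
        [
            [0.900, 0.100, 0.000, 0.000, 0.000],
            [0.090, 0.880, 0.010, 0.020, 0.000],
            [0.000, 0.010, 0.950, 0.040, 0.000],
            [0.000, 0.002, 0.004, 0.984, 0.010],
            [0.000, 0.000, 0.000, 0.020, 0.980],
        ]
    )
    return GroundTruthChain(t, DEFAULT_STATE_LABELS, lag_time)


def _traj_rng(seed: int, traj_index: int) -> np.random.Generator:
    # fixed per-trajectory substream: adding trajectories never changes
    # earlier ones
    return np.random.default_rng([int(seed), int(traj_index)])


def sample_discrete_trajectories(
    chain: GroundTruthChain,
    n_traj: int,
    n_steps: int,
    start_distribution=None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Sample integer state sequences by iterated categorical sampling."""
    t = chain.transition_matrix
    if start_distribution is None:
        start = np.zeros(chain.n_states)
        start[0] = 1.0
    else:
        start = np.asarray(start_distribution, dtype=float)
        if not np.isclose(start.sum(), 1.0, atol=1e-9):
            raise ValueError("start_distribution must sum to 1")
    cum = np.cumsum(t, axis=1)
    cum_start = np.cumsum(start)
    trajs = []
    for k in range(n_traj):
        rng = _traj_rng(seed, k)
        u = rng.random(n_steps)
        out = np.empty(n_steps, dtype=np.int64)
        s = int(np.searchsorted(cum_start, u[0], side="right"))
        out[0] = s
        for i in range(1, n_steps):
            s = int(np.searchsorted(cum[s], u[i], side="right"))
            out[i] = s
        trajs.append(out)
    return trajs


@dataclass
class MfptResult:
    steps: float
    time: float  # steps × lag_time, in the chain's time unit (μs)


def analytic_mfpt(chain: GroundTruthChain, source, target) -> MfptResult:
    """Exact mean first passage time via the absorbing-chain linear system."""
    src = chain.state_index(source)
    tgt = chain.state_index(target)
    if src == tgt:
        return MfptResult(0.0, 0.0)
    t = chain.transition_matrix
    n = chain.n_states
    keep = np.array([i for i in range(n) if i != tgt])
    q = t[np.ix_(keep, keep)]
    # unreachable target <=> (I - Q) singular on the source's component
    a = np.eye(len(keep)) - q
    try:
        m = np.linalg.solve(a, np.ones(len(keep)))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"target {target!r} unreachable from {source!r}") from exc
    if not np.isfinite(m).all() or (m < 0).any():
        raise ValueError(f"target {target!r} unreachable from {source!r}")
    steps = float(m[list(keep).index(src)])
    return MfptResult(steps, steps * chain.lag_time)


@dataclass
class ToyBindingParams:
    """Parameters of the toy overdamped-Langevin binding simulator.

    Units: Å for lengths, kcal/mol for energies, K for temperature,
    Å²/step for the diffusion coefficient.  ``flat_bottom_bounds`` is
    ``[x1, x2, y1, y2, z1, z2]`` (the restraint cuboid); outside the cuboid a
    force of magnitude ``flat_bottom_k × (distance beyond the boundary)``
    pulls the particle back toward the reference receptor site.
    """

    well_centers: np.ndarray
    well_depths: np.ndarray
    temperature: float = 298.0
    diffusion_coefficient: float = 0.05
    flat_bottom_bounds: tuple = (-20.0, 20.0, -20.0, 20.0, -20.0, 35.0)
    flat_bottom_k: float = 5.0
    well_width: float = 1.5
    n_steps: int = 10000
    seed: int = 0

    def __post_init__(self):
        self.well_centers = np.atleast_2d(np.asarray(self.well_centers, dtype=float))
        self.well_depths = np.atleast_1d(np.asarray(self.well_depths, dtype=float))
        if len(self.well_depths) != len(self.well_centers):
            raise ValueError("one depth per well center required")
        b = np.asarray(self.flat_bottom_bounds, dtype=float)
        if len(b) != 2 * self.well_centers.shape[1]:
            raise ValueError("flat_bottom_bounds needs two entries per dimension")
        lo, hi = b[0::2], b[1::2]
        if not (lo < hi).all():
            raise ValueError("flat-bottom bounds must satisfy lower < upper")
        if self.flat_bottom_k < 0:
            raise ValueError("flat_bottom_k must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


def _gaussian_well_force(x, centers, depths, width):
    # U = -sum_k depth_k exp(-|x-c_k|^2 / (2 w^2)); F = -dU/dx
    diff = x[None, :] - centers  # wells × dim
    r2 = (diff**2).sum(axis=1)
    g = depths * np.exp(-r2 / (2.0 * width**2))
    return -(g[:, None] * diff).sum(axis=0) / width**2


def simulate_toy_binding(params: ToyBindingParams, receptor_sites) -> Trajectory:
    """Euler–Maruyama trajectory of a single pseudo-ligand particle.

    The pseudo-receptor sites are fixed dummy Cα atoms; the returned
    :class:`Trajectory` carries them plus the moving ligand atom (a single
    nitrogen, residue ``LIG``), so the contact featurizer runs unchanged on
    toy data.  At ``temperature == 0`` the update degenerates to noiseless
    gradient descent with step ``D`` per unit force.
    """
    sites = np.atleast_2d(np.asarray(receptor_sites, dtype=float))
    if len(sites) < 1:
        raise ValueError("at least one receptor site required")
    d = params.diffusion_coefficient
    if d <= 0:
        raise ValueError("diffusion coefficient must be positive")
    dim = params.well_centers.shape[1]
    bounds = np.asarray(params.flat_bottom_bounds, dtype=float)
    lo, hi = bounds[0::2], bounds[1::2]
    ref = sites[0, :dim]
    rng = np.random.default_rng(int(params.seed))
    kt = R_KCAL * params.temperature
    mobility = d / kt if params.temperature > 0 else d
    noise_amp = np.sqrt(2.0 * d) if params.temperature > 0 else 0.0

    x = params.well_centers[0].copy()
    out = np.empty((params.n_steps + 1, dim))
    out[0] = x
    for i in range(1, params.n_steps + 1):
        force = _gaussian_well_force(x, params.well_centers, params.well_depths, params.well_width)
        excess = np.maximum(lo - x, 0.0) + np.maximum(x - hi, 0.0)
        d_out = np.linalg.norm(excess)
        if d_out > 0 and params.flat_bottom_k > 0:
            to_ref = ref - x
            nrm = np.linalg.norm(to_ref)
            if nrm > 1e-12:
                force = force + params.flat_bottom_k * d_out * to_ref / nrm
        x = x + mobility * force + noise_amp * rng.standard_normal(dim)
        out[i] = x

    # pack into a Trajectory: fixed sites as CA pseudo-residues + moving ligand N
    n_sites = len(sites)
    coords3 = np.zeros((params.n_steps + 1, n_sites + 1, 3))
    sites3 = np.zeros((n_sites, 3))
    sites3[:, : sites.shape[1]] = sites
    coords3[:, :n_sites, :] = sites3[None]
    coords3[:, n_sites, :dim] = out
    top = Topology(
        name=np.array(["CA"] * n_sites + ["N1"]),
        element=np.array(["C"] * n_sites + ["N"]),
        res_index=np.arange(n_sites + 1),
        res_seq=np.arange(1, n_sites + 2),
        res_name=np.array(["GLY"] * n_sites + ["LIG"]),
        chain_id=np.array(["A"] * n_sites + ["L"]),
        ligand_mask=np.array([False] * n_sites + [True]),
    )
    return Trajectory(top, coords3)


# --- minimal phenylalanine fragment ---------------------------------------

_BOND = {"N-CA": 1.458, "CA-CB": 1.530, "CB-CG": 1.502, "CG-CD1": 1.391}
_ANGLE = {"N-CA-CB": 110.5, "CA-CB-CG": 113.8, "CB-CG-CD1": 120.8}


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF internal-coordinate placement of atom d bonded to c."""
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    basis = np.column_stack([bc_hat, m_hat, n_hat])
    return c + basis @ d_local


def make_phe_fixture(chi1: float, chi2: float) -> StructureModel:
    """Minimal Phe fragment (N, CA, CB, CG, CD1) with requested χ1/χ2.

    Built with ideal bond geometry so that measuring the dihedrals recovers
    the requested values to machine precision.
    """
    for angle in (chi1, chi2):
        if not (-180.0 < angle <= 180.0):
            raise ValueError("chi angles must lie in (-180, 180]")
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND["N-CA"], 0.0, 0.0])
    # CB in the xy-plane at the ideal N-CA-CB angle
    ang = np.radians(180.0 - _ANGLE["N-CA-CB"])
    cb = ca + _BOND["CA-CB"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    cg = _place_atom(n, ca, cb, _BOND["CB-CG"], _ANGLE["CA-CB-CG"], chi1)
    cd1 = _place_atom(ca, cb, cg, _BOND["CG-CD1"], _ANGLE["CB-CG-CD1"], chi2)
    coords = np.array([n, ca, cb, cg, cd1])
    top = Topology(
        name=np.array(["N", "CA", "CB", "CG", "CD1"]),
        element=np.array(["N", "C", "C", "C", "C"]),
        res_index=np.zeros(5, dtype=int),
        res_seq=np.full(5, 1),
        res_name=np.array(["PHE"] * 5),
        chain_id=np.array(["A"] * 5),
    )
    return StructureModel(top, coords, source_id="phe-fixture")


@dataclass
class AssayTruth:
    """Ground truth for a simulated competition-binding assay."""

    ic50: float           # M
    hill: float = 1.0
    l_conc: float = 1e-9  # radioligand concentration, M
    kd: float = 1e-9      # radioligand dissociation constant, M
    noise_sd: float = 0.0  # % inhibition units
    seed: int = 0

    def __post_init__(self):
        if self.ic50 <= 0 or self.kd <= 0 or self.l_conc < 0:
            raise ValueError("concentrations must be positive (l_conc >= 0)")


def generate_dose_response(truth: AssayTruth, concentrations):
    """% inhibition = 100 / (1 + (IC50/c)^hill) plus seeded Gaussian noise.

    Returns a pandas DataFrame with columns ``concentration_M`` and
    ``inhibition_pct``.
    """
    import pandas as pd

    c = np.asarray(concentrations, dtype=float)
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    y = 100.0 / (1.0 + (truth.ic50 / c) ** truth.hill)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(int(truth.seed))
        y = y + rng.normal(0.0, truth.noise_sd, size=len(c))
    return pd.DataFrame({"concentration_M": c, "inhibition_pct": y})


# --- feature embedding of discrete chains ----------------------------------

def default_contact_templates(n_features: int = 20) -> np.ndarray:
    """Per-state template contact patterns over ``n_features`` residues.

    Bulk touches nothing; the vestibule contacts a surface patch; the
    intermediate, bound and off-pathway poses contact deeper, partially
    overlapping patches — a cartoon of poses occupying different parts of the
    same pocket.
    """
    if n_features < 12:
        raise ValueError("need at least 12 features for the default templates")
    t = np.zeros((5, n_features), dtype=np.uint8)
    q = n_features // 4
    t[1, :q] = 1                       # vestibule: outer patch
    t[2, q : 2 * q] = 1                # intermediate
    t[3, 2 * q - 1 : 3 * q + 1] = 1    # bound (overlaps intermediate edge)
    t[4, 3 * q :] = 1                  # off-pathway
    return t


def embed_contact_features(
    dtrajs: list[np.ndarray],
    n_features: int = 20,
    flip_prob: float = 0.05,
    bulk_state: int = 0,
    flag_error: float = 0.05,
    templates: np.ndarray | None = None,
    seed: int = 0,
) -> list[FeatureTrack]:
    """Emit noisy binary contact features + bulk flag from true state paths.

    Each frame takes its state's template contact vector with every bit
    flipped independently with probability ``flip_prob``; the bulk flag is 0
    for the bulk state and 1 otherwise, also flipped with ``flag_error``.
    """
    if templates is None:
        templates = default_contact_templates(n_features)
    tracks = []
    for k, dt in enumerate(dtrajs):
        rng = _traj_rng(seed + 1_000_000, k)
        base = templates[dt]
        flips = rng.random(base.shape) < flip_prob
        contact = np.where(flips, 1 - base, base).astype(np.uint8)
        flag = (dt != bulk_state).astype(np.uint8)
        flag_flips = rng.random(len(dt)) < flag_error
        flag = np.where(flag_flips, 1 - flag, flag).astype(np.uint8)
        tracks.append(FeatureTrack(contact, flag))
    return tracks
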