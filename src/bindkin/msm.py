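"""Markov state model estimation and metastable lumping.

The discretized trajectory (mini-batch k-means labels in TICA space) is
turned into a reversible maximum-likelihood Markov model on its largest
strongly connected set, lumped into metastable macrostates with a PCCA+-style
spectral method, split into an extra bulk macrostate using the bulk contact
flag, and optionally re-estimated on core sets with milestoning to suppress
spurious recrossings at cluster borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ClusterModel",
    "MarkovModel",
    "MacrostateMap",
    "cluster",
    "assign_clusters",
    "count_matrix",
    "trim_ergodic",
    "estimate_reversible",
    "implied_timescales",
    "pcca_lump",
    "split_bulk",
    "core_assign",
    "core_msm",
    "select_respawn_states",
]


@dataclass
class ClusterModel:
    """k-means centers with exact nearest-center (Euclidean) assignment."""

    centers: np.ndarray
    seed: int = 0

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or len(self.centers) < 2:
            raise ValueError("need a 2-D center array with k >= 2")
        if not np.isfinite(self.centers).all():
            raise ValueError("cluster centers must be finite")

    @property
    def k(self) -> int:
        return len(self.centers)

    def assign(self, x: np.ndarray) -> np.ndarray:
        return assign_clusters(self.centers, x)


def assign_clusters(centers: np.ndarray, x: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """Nearest-center labels, chunked to bound memory."""
    x = np.asarray(x, dtype=float)
    labels = np.empty(len(x), dtype=np.int64)
    c2 = (centers**2).sum(1)
    for s in range(0, len(x), chunk):
        block = x[s : s + chunk]
        d2 = c2[None, :] - 2.0 * block @ centers.T  # + |x|^2, constant per row
        labels[s : s + chunk] = np.argmin(d2, axis=1)
    return labels


def cluster(tica_coords: list[np.ndarray], k: int = 800, seed: int = 0):
    """Mini-batch k-means discretization of TICA space.

    Returns ``(ClusterModel, dtrajs)``; frames are assigned to the exact
    nearest center so the assignment rule is independent of the mini-batch
    fitting path.
    """
    from sklearn.cluster import MiniBatchKMeans

    data = np.concatenate([np.asarray(t, dtype=float) for t in tica_coords])
    if len(data) < k:
        raise ValueError(f"k={k} exceeds the total number of frames ({len(data)})")
    km = MiniBatchKMeans(
        n_clusters=k, random_state=int(seed), n_init=3, batch_size=4096, max_iter=200
    )
    km.fit(data)
    model = ClusterModel(km.cluster_centers_, seed=int(seed))
    dtrajs = [model.assign(np.asarray(t, dtype=float)) for t in tica_coords]
    return model, dtrajs


def count_matrix(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if n_states is None:
        n_states = max(int(d.max()) for d in dtrajs if len(d)) + 1
    c = np.zeros((n_states, n_states), dtype=float)
    any_pairs = False
    for d in dtrajs:
        if len(d) <= lag:
            continue
        any_pairs = True
        np.add.at(c, (d[:-lag], d[lag:]), 1.0)
    if not any_pairs:
        raise ValueError("lag is not shorter than any trajectory")
    return c


def trim_ergodic(counts: np.ndarray):
    """Largest strongly connected component of the count graph.

    Returns ``(active_set, counts_restricted)``; ties between equally sized
    components are broken by total count mass.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty count matrix")
    n_comp, labels = connected_components(csr_matrix(counts > 0), connection="strong")
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        key = (len(members), counts[np.ix_(members, members)].sum())
        if best_key is None or key > best_key:
            best, best_key = members, key
    active = np.sort(best)
    return active, counts[np.ix_(active, active)]


@dataclass
class MarkovModel:
    """Reversible MSM: counts, transition matrix, stationary vector, spectrum.

    ``lag`` is in frames; ``frame_interval`` carries the physical time per
    frame so implied timescales and MFPTs can be reported in physical units.
    """

    lag: int
    counts: np.ndarray
    active_set: np.ndarray
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    frame_interval: float = 1.0
    eigenvalues: np.ndarray = field(default=None)

    def __post_init__(self):
        t = self.transition_matrix
        if not np.allclose(t.sum(1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        pi = self.stationary_distribution
        flux = pi[:, None] * t
        scale = np.maximum(np.abs(flux), np.abs(flux.T))
        bad = scale > 1e-300
        if not np.allclose(flux[bad] / scale[bad], flux.T[bad] / scale[bad], atol=1e-8):
            raise ValueError("detailed balance violated beyond tolerance")
        if self.eigenvalues is None:
            self.eigenvalues = _reversible_spectrum(t, pi)[0]

    @property
    def n_states(self) -> int:
        return len(self.transition_matrix)

    def implied_timescales(self, n_timescales: int = 5) -> np.ndarray:
        """t_i = −lag/ln λ_i (physical units); non-positive λ → NaN."""
        lam = self.eigenvalues[1 : n_timescales + 1]
        out = np.full(len(lam), np.nan)
        ok = (lam > 0) & (lam < 1)
        if (~ok).any():
            warnings.warn("non-positive eigenvalues: timescales undefined", stacklevel=2)
        out[ok] = -self.lag * self.frame_interval / np.log(lam[ok])
        return out


def _reversible_spectrum(t: np.ndarray, pi: np.ndarray):
    """Real sorted spectrum of a reversible transition matrix."""
    sqrt_pi = np.sqrt(pi)
    sym = (sqrt_pi[:, None] * t) / sqrt_pi[None, :]
    sym = 0.5 * (sym + sym.T)
    lam, phi = np.linalg.eigh(sym)
    order = np.argsort(lam)[::-1]
    lam, phi = lam[order], phi[:, order]
    right = phi / sqrt_pi[:, None]  # right eigenvectors of T
    return lam, right


def estimate_reversible(
    counts: np.ndarray,
    lag: int = 1,
    frame_interval: float = 1.0,
    active_set: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> MarkovModel:
    """Maximum-likelihood reversible transition matrix.

    Fixed-point iteration on the symmetric flow matrix ``x``:
    ``x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j)``, converged when the
    largest relative change is below ``tol``.  π comes from the row sums
    of ``x``.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape[0] != c.shape[1]:
        raise ValueError("count matrix must be square")
    n = c.shape[0]
    if active_set is None:
        active_set = np.arange(n)
    if n == 1:
        return MarkovModel(lag, c, np.asarray(active_set), np.ones((1, 1)),
                           np.ones(1), frame_interval)
    c_sym = c + c.T
    if (c_sym.sum(1) == 0).any():
        raise ValueError("count matrix has unvisited states; trim first")
    c_row = c.sum(1)
    x = c_sym / c_sym.sum()
    for it in range(max_iter):
        x_row = x.sum(1)
        denom = c_row[:, None] / x_row[:, None] + c_row[None, :] / x_row[None, :]
        x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x) / np.maximum(x, 1e-300))
        x = x_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"reversible estimator failed to converge in {max_iter} iterations "
            f"(last relative change {delta:.2e})"
        )
    pi = x.sum(1)
    t = x / pi[:, None]
    t = t / t.sum(1, keepdims=True)
    return MarkovModel(lag, c, np.asarray(active_set), t, pi / pi.sum(), frame_interval)


def implied_timescales(dtrajs, lags, n_timescales: int = 5, frame_interval: float = 1.0):
    """Implied-timescale table over candidate lags (plateau → working lag).

    Returns a pandas DataFrame indexed by lag; lags whose estimation fails
    are skipped with a warning.
    """
    import pandas as pd

    rows = {}
    for lag in lags:
        try:
            c = count_matrix(dtrajs, lag)
            active, c_act = trim_ergodic(c)
            model = estimate_reversible(c_act, lag=lag, frame_interval=frame_interval,
                                        active_set=active)
            rows[lag] = model.implied_timescales(n_timescales)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"lag {lag}: estimation failed ({exc}); skipped", stacklevel=2)
    if not rows:
        raise ValueError("no lag could be estimated")
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"t{i+2}" for i in range(n_timescales)],
    ).rename_axis("lag")


@dataclass
class MacrostateMap:
    """Cluster→macrostate assignment with fuzzy memberships and cores."""

    n_macro: int
    active_set: np.ndarray            # original cluster ids (sorted)
    labels: np.ndarray                # per active cluster, crisp macrostate
    memberships: np.ndarray           # active clusters × macrostates
    bulk_id: int | None = None
    cores: dict = field(default_factory=dict)  # macrostate -> active-cluster positions

    def __post_init__(self):
        m = self.memberships
        if m.shape != (len(self.active_set), self.n_macro):
            raise ValueError("membership matrix shape mismatch")
        if not np.allclose(m.sum(1), 1.0, atol=1e-10):
            raise ValueError("membership rows must sum to 1")
        if (m < -1e-12).any():
            raise ValueError("memberships must be non-negative")

    def cluster_position(self) -> dict:
        """original cluster id → position in active_set"""
        return {int(c): i for i, c in enumerate(self.active_set)}

    def macro_trajectories(self, dtrajs) -> list[np.ndarray]:
        """Map cluster trajectories to macrostate labels (−1 = inactive)."""
        lut = np.full(int(max(self.active_set.max(), max(int(d.max()) for d in dtrajs))) + 1, -1,
                      dtype=np.int64)
        lut[self.active_set] = self.labels
        return [lut[np.asarray(d, dtype=np.int64)] for d in dtrajs]


def pcca_lump(model: MarkovModel, n_macro: int = 4) -> MacrostateMap:
    """PCCA+-style lumping of microstates into metastable macrostates.

    Spectral coordinates are the top ``n_macro`` right eigenvectors; simplex
    vertices are found by furthest-point (inner simplex) seeding, memberships
    by the linear transform mapping vertices to unit vectors, clipped to
    [0, 1] and row-normalized.  Crisp labels are the argmax memberships.
    """
    if n_macro < 1 or n_macro > model.n_states:
        raise ValueError("n_macro must be in [1, n_states]")
    lam, right = _reversible_spectrum(model.transition_matrix, model.stationary_distribution)
    psi = right[:, :n_macro].copy()
    psi[:, 0] = 1.0  # constant eigenvector, fixed normalization

    # inner-simplex vertex search
    vertices = [int(np.argmax(np.linalg.norm(psi - psi.mean(0), axis=1)))]
    ortho = psi - psi[vertices[0]]
    for _ in range(1, n_macro):
        norms = np.linalg.norm(ortho, axis=1)
        nxt = int(np.argmax(norms))
        vertices.append(nxt)
        v = ortho[nxt]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        ortho = ortho - np.outer(ortho @ v, v) / nv**2
    a = np.linalg.pinv(psi[vertices])
    chi = psi @ a
    chi = np.clip(chi, 0.0, 1.0)
    rowsum = chi.sum(1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    chi = chi / rowsum
    labels = np.argmax(chi, axis=1)
    return MacrostateMap(
        n_macro=n_macro,
        active_set=model.active_set,
        labels=labels.astype(np.int64),
        memberships=chi,
    )


def split_bulk(mmap: MacrostateMap, dtrajs, bulk_flags) -> MacrostateMap:
    """Split an extra bulk macrostate out using the bulk contact flag.

    A cluster moves to the new bulk macrostate iff the majority (≥ 50%, ties
    to bulk) of its frames have flag 0 (ligand in bulk).
    """
    flags = [np.asarray(f) for f in bulk_flags]
    if any(len(f) != len(d) for f, d in zip(flags, dtrajs)):
        raise ValueError("bulk flags must align frame-wise with dtrajs")
    n_clusters = int(max(int(np.max(d)) for d in dtrajs)) + 1
    total = np.zeros(n_clusters)
    in_bulk = np.zeros(n_clusters)
    for d, f in zip(dtrajs, flags):
        np.add.at(total, d, 1.0)
        np.add.at(in_bulk, d, (np.asarray(f) == 0).astype(float))
    if in_bulk.sum() == 0:
        warnings.warn("no bulk frames at all; map unchanged", stacklevel=2)
        return mmap
    bulk_frac = np.zeros(len(mmap.active_set))
    for i, c in enumerate(mmap.active_set):
        if c < n_clusters and total[c] > 0:
            bulk_frac[i] = in_bulk[c] / total[c]
    is_bulk = bulk_frac >= 0.5
    bulk_id = mmap.n_macro
    labels = mmap.labels.copy()
    labels[is_bulk] = bulk_id
    chi = np.zeros((len(mmap.active_set), mmap.n_macro + 1))
    chi[:, : mmap.n_macro] = mmap.memberships
    chi[is_bulk] = 0.0
    chi[is_bulk, bulk_id] = 1.0
    return MacrostateMap(
        n_macro=mmap.n_macro + 1,
        active_set=mmap.active_set,
        labels=labels,
        memberships=chi,
        bulk_id=bulk_id,
    )


def core_assign(mmap: MacrostateMap, dtrajs, membership_threshold: float = 0.9,
                bulk_flags=None):
    """Milestoning assignment onto macrostate cores at cluster granularity.

    Cores are clusters whose macrostate membership is ≥ the threshold; a
    macrostate with an empty core falls back to its maximum-membership
    cluster (with a warning).  Frames outside every core keep the label of
    the last visited core cluster; frames before the first core visit are
    dropped.

    When ``bulk_flags`` are given and the map has a bulk macrostate, a frame
    is additionally required to be *consistent* between the two contact
    representations to count as a core visit: its flag must read bulk (0)
    exactly when its cluster belongs to the bulk macrostate.  Contradictory
    frames (e.g. an interacting-pose frame whose contact pattern momentarily
    reads as bulk) are treated as excursions and milestoned over, suppressing
    single-frame spurious transitions.

    Returns ``(core_dtrajs, core_clusters, core_macro_labels)`` where
    ``core_dtrajs`` label frames by position into ``core_clusters`` (original
    cluster ids) and ``core_macro_labels`` give each core cluster's
    macrostate.
    """
    chi = mmap.memberships
    core_positions = []
    core_macros = []
    for m in range(mmap.n_macro):
        members = np.flatnonzero(mmap.labels == m)
        if len(members) == 0:
            continue
        strong = members[chi[members, m] >= membership_threshold]
        if len(strong) == 0:
            best = members[int(np.argmax(chi[members, m]))]
            warnings.warn(
                f"macrostate {m}: empty core at threshold {membership_threshold}; "
                "falling back to its maximum-membership cluster",
                stacklevel=2,
            )
            strong = np.array([best])
        core_positions.extend(strong.tolist())
        core_macros.extend([m] * len(strong))
    core_positions = np.asarray(core_positions, dtype=int)
    order = np.argsort(core_positions)
    core_positions, core_macros = core_positions[order], np.asarray(core_macros)[order]
    core_clusters = mmap.active_set[core_positions]

    # original cluster id → core index (or −1)
    size = int(max(mmap.active_set.max(), max(int(d.max()) for d in dtrajs))) + 1
    lut = np.full(size, -1, dtype=np.int64)
    lut[core_clusters] = np.arange(len(core_clusters))

    bulk_cluster = np.zeros(size, dtype=bool)
    if mmap.bulk_id is not None:
        bulk_cluster[mmap.active_set[mmap.labels == mmap.bulk_id]] = True

    core_dtrajs = []
    for j, d in enumerate(dtrajs):
        d = np.asarray(d, dtype=np.int64)
        raw = lut[d]
        if bulk_flags is not None and mmap.bulk_id is not None:
            flags = np.asarray(bulk_flags[j])
            inconsistent = (flags == 0) != bulk_cluster[d]
            raw = np.where(inconsistent, -1, raw)
        out = raw.copy()
        last = -1
        for i in range(len(raw)):
            if raw[i] >= 0:
                last = raw[i]
            out[i] = last
        first = np.argmax(out >= 0) if (out >= 0).any() else len(out)
        core_dtrajs.append(out[first:])
    return core_dtrajs, core_clusters, core_macros


def core_msm(
    mmap: MacrostateMap,
    dtrajs,
    lag: int,
    frame_interval: float = 1.0,
    membership_threshold: float = 0.9,
    bulk_flags=None,
):
    """Re-estimate the reversible MSM on core-labeled trajectories.

    Returns ``(model, core_clusters, core_macro_labels)``; the model's states
    are the core clusters (in ``core_clusters`` order, restricted to the
    largest connected set).
    """
    core_dtrajs, core_clusters, core_macros = core_assign(
        mmap, dtrajs, membership_threshold, bulk_flags=bulk_flags
    )
    c = count_matrix(core_dtrajs, lag, n_states=len(core_clusters))
    active, c_act = trim_ergodic(c)
    model = estimate_reversible(c_act, lag=lag, frame_interval=frame_interval,
                                active_set=active)
    return model, core_clusters[active], core_macros[active]


def select_respawn_states(counts, n_new: int, seed: int = 0) -> np.ndarray:
    """Adaptive-sampling respawn: sample clusters with weight ∝ 1/(1+count).

    Under-visited clusters are favoured as restart points for the next epoch;
    all-zero counts reduce to uniform sampling.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    w = 1.0 / (1.0 + counts)
    w = w / w.sum()
    rng = np.random.default_rng(int(seed))
    return rng.choice(len(counts), size=n_new, replace=True, p=w)
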