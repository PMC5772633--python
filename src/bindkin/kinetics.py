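"""Binding kinetics and thermodynamics from the macrostate model.

Headline quantities:

* **MFPT** between macrostates from the cluster-level (or core-level)
  transition matrix: solve ``m_i = τ + Σ_j T_ij m_j`` with ``m = 0`` on the
  target clusters; the source value is the π-weighted average over the source
  macrostate's clusters.
* **k_on** with the effective-concentration correction for a single ligand
  copy confined to the flat-bottom restraint volume:
  ``C_eff = 1/(N_A·V)`` and ``k_on = 1/(MFPT_on · C_eff)``.
* **Per-state free energies** relative to bulk, ``ΔG_s = −RT ln(π_s/π_bulk)``,
  optionally with the standard-state shift ``+RT ln(C_eff/1 M)``.
* **Pathway fractions**: a binding event is the segment from the last bulk
  visit to the first bound visit; it is *indirect* iff it passes a marker
  (intermediate) macrostate.
* **Bootstrap errors** by resampling trajectories with replacement and
  re-running the estimation from the count matrix onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import msm as _msm

__all__ = [
    "R_KCAL",
    "N_AVOGADRO",
    "FlatBottomBox",
    "KineticsReport",
    "mfpt_states",
    "mfpt",
    "box_volume",
    "effective_concentration",
    "k_on",
    "state_free_energies",
    "classify_binding_pathways",
    "bootstrap_errors",
    "macrostate_populations",
]

R_KCAL = 1.98720e-3       # kcal/(mol K)
N_AVOGADRO = 6.02214e23   # 1/mol


@dataclass
class FlatBottomBox:
    """Cuboid flat-bottom restraint: bounds [x1,x2,y1,y2,z1,z2] in Å."""

    bounds: tuple = (-20.0, 20.0, -20.0, 20.0, -20.0, 35.0)
    force_constant: float = 5.0  # kcal/(mol Å²)

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=float)
        if len(b) != 6 or not (b[0::2] < b[1::2]).all():
            raise ValueError("bounds must be [x1,x2,y1,y2,z1,z2] with lower < upper")


def box_volume(box: FlatBottomBox) -> float:
    """Volume of the restraint cuboid in nm³ (10³ Å³ = 1 nm³)."""
    b = np.asarray(box.bounds, dtype=float)
    sides = b[1::2] - b[0::2]
    return float(np.prod(sides) / 1000.0)


def effective_concentration(volume_nm3: float) -> float:
    """Molar concentration of one molecule in ``volume_nm3`` (1 nm³ = 1e-24 L)."""
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    return 1.0 / (N_AVOGADRO * volume_nm3 * 1e-24)


def k_on(mfpt_on_s: float, c_eff: float) -> float:
    """Association rate constant, k_on = 1/(MFPT_on · C_eff) in M⁻¹s⁻¹."""
    if mfpt_on_s <= 0 or c_eff <= 0:
        raise ValueError("MFPT and effective concentration must be positive")
    return 1.0 / (mfpt_on_s * c_eff)


def mfpt_states(
    transition_matrix: np.ndarray,
    source_states,
    target_states,
    stationary_distribution=None,
    lag: int = 1,
    frame_interval: float = 1.0,
) -> float:
    """MFPT (physical time) from a set of source states to a target set.

    Solves the absorbing linear system at the model's lag; the source value
    is the π-weighted average over the source states (uniform if no π given).
    Source states inside the target give 0 by convention.
    """
    t = np.asarray(transition_matrix, dtype=float)
    n = len(t)
    source = np.atleast_1d(np.asarray(source_states, dtype=int))
    target = np.unique(np.atleast_1d(np.asarray(target_states, dtype=int)))
    free = np.setdiff1d(np.arange(n), target)
    m = np.zeros(n)
    if len(free):
        a = np.eye(len(free)) - t[np.ix_(free, free)]
        try:
            sol = np.linalg.solve(a, np.full(len(free), float(lag)))
        except np.linalg.LinAlgError as exc:
            raise ValueError("target set unreachable from part of the chain") from exc
        if not np.isfinite(sol).all() or (sol < -1e-9).any():
            raise ValueError("target set unreachable from part of the chain")
        m[free] = sol
    if stationary_distribution is None:
        w = np.ones(len(source))
    else:
        w = np.asarray(stationary_distribution, dtype=float)[source]
    if w.sum() <= 0:
        raise ValueError("source states carry zero stationary weight")
    return float((m[source] * w).sum() / w.sum() * frame_interval)


def mfpt(model: _msm.MarkovModel, state_labels: np.ndarray, source_macro: int,
         target_macro: int) -> float:
    """Macrostate MFPT on a cluster-level model.

    ``state_labels`` gives the macrostate of each model state (cluster).
    """
    if source_macro == target_macro:
        return 0.0
    src = np.flatnonzero(state_labels == source_macro)
    tgt = np.flatnonzero(state_labels == target_macro)
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("source or target macrostate has no clusters in the model")
    return mfpt_states(
        model.transition_matrix, src, tgt,
        stationary_distribution=model.stationary_distribution,
        lag=model.lag, frame_interval=model.frame_interval,
    )


def macrostate_populations(model: _msm.MarkovModel, state_labels: np.ndarray,
                           n_macro: int) -> np.ndarray:
    """Aggregate the stationary distribution over macrostates."""
    pi = np.zeros(n_macro)
    for m in range(n_macro):
        pi[m] = model.stationary_distribution[state_labels == m].sum()
    return pi


def state_free_energies(
    pi_macro: np.ndarray,
    bulk_id: int,
    temperature: float = 298.0,
    c_eff: float | None = None,
):
    """ΔG_s = −RT ln(π_s/π_bulk) per macrostate (kcal/mol, bulk = 0).

    Returns ``(delta_g, delta_g_standard)``; the standard-state column adds
    ``RT ln(C_eff / 1 M)`` and is None unless ``c_eff`` is given.  States with
    zero population get +inf with a warning.
    """
    pi = np.asarray(pi_macro, dtype=float)
    if not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise ValueError("macrostate populations must sum to 1")
    if pi[bulk_id] <= 0:
        raise ValueError("bulk population must be positive")
    rt = R_KCAL * temperature
    with np.errstate(divide="ignore"):
        dg = -rt * np.log(pi / pi[bulk_id])
    if np.isinf(dg).any():
        warnings.warn("zero-population macrostate: ΔG = +inf", stacklevel=2)
    dg_std = dg + rt * np.log(c_eff) if c_eff is not None else None
    return dg, dg_std


def classify_binding_pathways(macro_trajs, bulk_id: int, bound_id: int, marker_ids):
    """Fractions of direct vs indirect binding events.

    A binding event is the maximal segment from the last bulk visit to the
    first subsequent bound visit; it is indirect iff any marker macrostate
    appears strictly inside the segment.  Returns a dict with ``direct``,
    ``indirect`` fractions and ``n_events``.
    """
    markers = set(int(m) for m in np.atleast_1d(marker_ids))
    n_direct = n_indirect = 0
    for traj in macro_trajs:
        traj = np.asarray(traj)
        last_bulk = None
        for i, s in enumerate(traj):
            if s == bulk_id:
                last_bulk = i
            elif s == bound_id and last_bulk is not None:
                segment = traj[last_bulk + 1 : i]
                if any(int(x) in markers for x in segment):
                    n_indirect += 1
                else:
                    n_direct += 1
                last_bulk = None  # must revisit bulk before the next event
    n_events = n_direct + n_indirect
    if n_events == 0:
        warnings.warn("no complete bulk→bound events found", stacklevel=2)
        return {"direct": np.nan, "indirect": np.nan, "n_events": 0}
    return {
        "direct": n_direct / n_events,
        "indirect": n_indirect / n_events,
        "n_events": n_events,
    }


def bootstrap_errors(trajectories, compute_fn, n_boot: int = 100, seed: int = 0):
    """Trajectory bootstrap of arbitrary scalar summaries.

    ``compute_fn`` maps a list of trajectories to a dict of floats; replicates
    raising ``ValueError``/``RuntimeError`` (e.g. no bulk→bound connectivity
    in a resample) are skipped and counted, with a warning above 20% skips.
    Returns ``(standard_errors, n_skipped)``.
    """
    trajectories = list(trajectories)
    if len(trajectories) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    rng = np.random.default_rng(int(seed))
    samples: dict[str, list[float]] = {}
    n_skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(trajectories), size=len(trajectories))
        try:
            result = compute_fn([trajectories[i] for i in idx])
        except (ValueError, RuntimeError):
            n_skipped += 1
            continue
        for key, val in result.items():
            samples.setdefault(key, []).append(float(val))
    if n_skipped > 0.2 * n_boot:
        warnings.warn(f"{n_skipped}/{n_boot} bootstrap replicates skipped", stacklevel=2)
    ses = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in samples.items()}
    return ses, n_skipped


@dataclass
class KineticsReport:
    """Headline kinetics/thermodynamics with bootstrap standard errors."""

    mfpt: np.ndarray              # macrostate × macrostate, physical time
    mfpt_on: float                # bulk → bound
    c_eff: float                  # M
    k_on: float                   # 1/(mfpt_on[s] × c_eff)
    delta_g: np.ndarray           # per macrostate, kcal/mol, bulk = 0
    delta_g_standard: np.ndarray | None
    pathway_fractions: dict
    populations: np.ndarray
    errors: dict = field(default_factory=dict)
    time_unit_seconds: float = 1.0  # conversion of mfpt units to seconds

    def __post_init__(self):
        if self.mfpt_on <= 0:
            raise ValueError("MFPT_on must be positive")
        expected = 1.0 / (self.mfpt_on * self.time_unit_seconds * self.c_eff)
        if abs(self.k_on - expected) > 1e-10 * expected:
            raise ValueError("k_on inconsistent with 1/(MFPT_on × C_eff)")


def kinetics_report(
    model: _msm.MarkovModel,
    state_labels: np.ndarray,
    n_macro: int,
    bulk_id: int,
    bound_id: int,
    marker_ids,
    macro_trajs,
    box: FlatBottomBox,
    temperature: float = 298.0,
    time_unit_seconds: float = 1e-6,
) -> KineticsReport:
    """Assemble the full report from a cluster-level model.

    ``time_unit_seconds`` converts the model's physical time unit (per
    ``frame_interval``) into seconds; the default treats it as μs.
    """
    mf = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        for b in range(n_macro):
            if a != b:
                mf[a, b] = mfpt(model, state_labels, a, b)
    mfpt_on = mf[bulk_id, bound_id]
    c_eff = effective_concentration(box_volume(box))
    kon = k_on(mfpt_on * time_unit_seconds, c_eff)
    pops = macrostate_populations(model, state_labels, n_macro)
    dg, dg_std = state_free_energies(pops, bulk_id, temperature, c_eff)
    fractions = classify_binding_pathways(macro_trajs, bulk_id, bound_id, marker_ids)
    return KineticsReport(
        mfpt=mf,
        mfpt_on=mfpt_on,
        c_eff=c_eff,
        k_on=kon,
        delta_g=dg,
        delta_g_standard=dg_std,
        pathway_fractions=fractions,
        populations=pops,
        time_unit_seconds=time_unit_seconds,
    )
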