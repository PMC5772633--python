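"""Time-lagged independent component analysis (TICA).

Projects feature time series onto the slowest linear collective coordinates:
solve the generalized eigenproblem ``C_tau v = λ C_0 v`` with the symmetrized
time-lagged covariance ``C_tau`` and the instantaneous covariance ``C_0``,
both pooled over trajectories with a sliding window.  Symmetrization makes
the estimate invariant under time reversal, and the eigenvalues equal the
autocorrelations of the corresponding components at the chosen lag.

Rank deficiency in ``C_0`` (constant or linearly dependent features, common
for binary contact data) is handled by solving in the subspace of ``C_0``
eigenvalues above ``epsilon × λ_max``.  No kinetic-map scaling is applied:
outputs are plain eigenvector projections with unit ``C_0`` norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TicaModel", "fit_tica", "transform"]


@dataclass
class TicaModel:
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    lag: int
    eigenvalues: np.ndarray   # descending
    components: np.ndarray    # columns; unit C0-norm
    n_components: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        return transform(self, x)


def _as_float_tracks(feature_tracks):
    out = []
    for t in feature_tracks:
        arr = getattr(t, "contact_matrix", t)
        out.append(np.asarray(arr, dtype=float))
    return out


def fit_tica(feature_tracks, lag: int, n_components: int = 5, epsilon: float = 1e-8) -> TicaModel:
    """Fit TICA on a list of (frames × features) matrices.

    ``feature_tracks`` may be raw arrays or :class:`~bindkin.featurize.FeatureTrack`
    objects (their contact matrices are used).
    """
    tracks = _as_float_tracks(feature_tracks)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if any(len(t) <= lag for t in tracks):
        raise ValueError("every trajectory must be longer than the lag")
    dim = tracks[0].shape[1]
    if any(t.shape[1] != dim for t in tracks):
        raise ValueError("inconsistent feature dimensions")

    # pooled sliding-window pairs; mean over both windows for exact
    # time-reversal symmetry of the estimator
    x0 = np.concatenate([t[:-lag] for t in tracks])
    xt = np.concatenate([t[lag:] for t in tracks])
    n = len(x0)
    mean = (x0.sum(0) + xt.sum(0)) / (2.0 * n)
    a, b = x0 - mean, xt - mean
    c0 = (a.T @ a + b.T @ b) / (2.0 * n)
    ctau = (a.T @ b + b.T @ a) / (2.0 * n)

    evals0, evecs0 = np.linalg.eigh(c0)
    if evals0[-1] <= 0:
        raise ValueError("all features are constant; TICA undefined")
    keep = evals0 > epsilon * evals0[-1]
    if keep.sum() < 1:
        raise ValueError("covariance matrix has no usable rank")
    whiten = evecs0[:, keep] / np.sqrt(evals0[keep])
    m = whiten.T @ ctau @ whiten
    m = 0.5 * (m + m.T)
    lam, u = np.linalg.eigh(m)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]
    comps = whiten @ u  # v^T C0 v = 1 automatically

    k = min(n_components, comps.shape[1])
    return TicaModel(
        mean=mean,
        c0=c0,
        ctau=ctau,
        lag=int(lag),
        eigenvalues=lam[:k],
        components=comps[:, :k],
        n_components=k,
    )


def transform(model: TicaModel, x) -> np.ndarray:
    """Project data onto the stored components (deterministic)."""
    arr = np.asarray(getattr(x, "contact_matrix", x), dtype=float)
    if arr.shape[1] != len(model.mean):
        raise ValueError(
            f"feature dimension {arr.shape[1]} does not match model ({len(model.mean)})"
        )
    return (arr - model.mean) @ model.components
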