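"""Radioligand competition-binding arithmetic.

IC50 curve fitting of percent-inhibition dose responses, Cheng–Prusoff
conversion to inhibition constants ``K_i = IC50/(1 + L/K_d)``, mutant/wt
fold shifts (values > 1 indicate the mutation weakens binding), and binding
free energy ``ΔG = RT ln(K_i / 1 M)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_KCAL = 1.98720e-3  # kcal/(mol K)

__all__ = [
    "AssayRecord",
    "FoldShift",
    "Ic50Fit",
    "fit_ic50",
    "cheng_prusoff",
    "fold_shift",
    "delta_g_from_ki",
    "process_assay_table",
]


@dataclass
class AssayRecord:
    compound: str
    receptor_form: str = "wt"
    ic50: float | None = None   # M
    l_conc: float | None = None  # M
    kd: float | None = None     # M
    ki: float | None = None     # M

    def __post_init__(self):
        for name in ("ic50", "kd", "ki"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.l_conc is not None and self.l_conc < 0:
            raise ValueError("l_conc must be non-negative")
        if all(v is not None for v in (self.ic50, self.l_conc, self.kd)):
            expected = cheng_prusoff(self.ic50, self.l_conc, self.kd)
            if self.ki is None:
                self.ki = expected
            elif abs(self.ki - expected) > 0.05 * expected:
                raise ValueError(
                    f"ki={self.ki} inconsistent with Cheng–Prusoff value {expected:.3g}"
                )


@dataclass
class FoldShift:
    compound: str
    mutation: str
    ratio: float

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("fold shift must be positive")


@dataclass
class Ic50Fit:
    ic50: float
    hill: float
    residual_rms: float
    flagged: bool
    message: str = ""


def _logistic(c, ic50, hill):
    return 100.0 / (1.0 + (ic50 / c) ** hill)


def fit_ic50(concentrations, inhibition) -> Ic50Fit:
    """Least-squares fit of % inhibition = 100/(1 + (IC50/c)^hill).

    The initial IC50 guess is the concentration whose response is nearest
    50%.  Fits that do not converge, or whose IC50 falls outside the tested
    range scaled by [0.01, 100], are flagged rather than raised.
    """
    from scipy.optimize import curve_fit

    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 concentration points")
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.ptp(y) < 1.0:
        return Ic50Fit(np.nan, np.nan, np.nan, True, "no transition in the data")
    # fit log10(IC50) so both parameters have comparable scale
    def model(conc, log_ic50, hill):
        return _logistic(conc, 10.0**log_ic50, hill)

    p0 = [np.log10(c[int(np.argmin(np.abs(y - 50.0)))]), 1.0]
    try:
        popt, _ = curve_fit(
            model, c, y, p0=p0,
            bounds=([-300.0, 0.05], [300.0, 20.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20_000,
        )
    except RuntimeError as exc:
        return Ic50Fit(np.nan, np.nan, np.nan, True, f"fit failed: {exc}")
    ic50, hill = float(10.0 ** popt[0]), float(popt[1])
    popt = (ic50, hill)
    rms = float(np.sqrt(np.mean((_logistic(c, *popt) - y) ** 2)))
    flagged = not (0.01 * c.min() <= ic50 <= 100.0 * c.max())
    msg = "ic50 outside tested range window" if flagged else ""
    return Ic50Fit(ic50, hill, rms, flagged, msg)


def cheng_prusoff(ic50: float, l_conc: float, kd: float) -> float:
    """K_i = IC50 / (1 + L/K_d)."""
    if ic50 <= 0 or kd <= 0 or l_conc < 0:
        raise ValueError("require ic50 > 0, kd > 0, l_conc >= 0")
    return ic50 / (1.0 + l_conc / kd)


def fold_shift(ki_mut: float, ki_wt: float) -> float:
    """K_i^mutant / K_i^wt; > 1 means the mutation weakens binding."""
    if ki_mut <= 0 or ki_wt <= 0:
        raise ValueError("inhibition constants must be positive")
    return ki_mut / ki_wt


def delta_g_from_ki(ki: float, temperature: float = 298.0) -> float:
    """Binding free energy ΔG = RT ln(K_i / 1 M) in kcal/mol (negative for
    sub-molar affinity)."""
    if ki <= 0 or temperature <= 0:
        raise ValueError("ki and temperature must be positive")
    return R_KCAL * temperature * np.log(ki)


def process_assay_table(df, temperature: float = 298.0):
    """Vectorized assay processing of a DataFrame.

    Expects columns ``compound``, ``receptor_form``, ``ic50_nM``, ``L_nM``,
    ``kd_nM``; adds ``ki_nM``, ``delta_g_kcal_mol`` and, for mutant rows with
    a wt row of the same compound, ``fold_shift``.
    """
    out = df.copy()
    out["ki_nM"] = [
        cheng_prusoff(r.ic50_nM * 1e-9, r.L_nM * 1e-9, r.kd_nM * 1e-9) * 1e9
        for r in out.itertuples()
    ]
    out["delta_g_kcal_mol"] = [
        delta_g_from_ki(k * 1e-9, temperature) for k in out["ki_nM"]
    ]
    wt_ki = {
        r.compound: r.ki_nM
        for r in out.itertuples()
        if str(r.receptor_form).lower() == "wt"
    }
    shifts = []
    for r in out.itertuples():
        if str(r.receptor_form).lower() != "wt" and r.compound in wt_ki:
            shifts.append(fold_shift(r.ki_nM, wt_ki[r.compound]))
        else:
            shifts.append(np.nan)
    out["fold_shift"] = shifts
    return out
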