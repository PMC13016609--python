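"""Fluorescence anisotropy: Hill binding fits and replicate combination.

Anisotropy r = (I_par - I_perp) / (I_par + 2 I_perp) rises as labelled DNA is
bound by protein.  A titration of protein concentration x is fit to the Hill
isotherm

    r(x) = r_f + r_b * x^n / (K_D^n + x^n)

where r_f is the free-DNA baseline, r_b the bound-DNA amplitude, K_D the
dissociation constant (nM) and n the Hill cooperativity coefficient.
Per-replicate parameter variances come from the covariance diagonal of the
least-squares fit, and replicates are combined by the inverse-variance
weighted mean with its weighted standard error (including the m/(m-1)
small-sample factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TitrationCurve",
    "HillFit",
    "WeightedEstimate",
    "anisotropy_from_intensities",
    "hill_model",
    "fit_hill",
    "weighted_combine",
    "fit_titration_table",
]

BOUNDS = {"r_f": (0.0, 1.0), "r_b": (0.0, 1.0),
          "K_D": (1e-3, 1e3), "n": (0.2, 10.0)}


@dataclass
class TitrationCurve:
    sequence_id: str
    concentrations: np.ndarray  # nM, ascending, includes 0
    r: np.ndarray  # anisotropy per point
    replicate_id: str = "rep1"
    uv_treated: bool = False

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.r = np.asarray(self.r, float)
        if self.concentrations.shape != self.r.shape:
            raise ValueError("concentrations and r must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class HillFit:
    K_D: float
    n: float
    r_f: float
    r_b: float
    var_KD: float
    var_n: float
    converged: bool
    rss: float = np.nan


@dataclass
class WeightedEstimate:
    x_wtd: float
    se_wtd: float
    m: int


def anisotropy_from_intensities(I_parallel, I_perpendicular):
    """r = (I_par - I_perp) / (I_par + 2 I_perp), elementwise."""
    ipar = np.asarray(I_parallel, float)
    iperp = np.asarray(I_perpendicular, float)
    denom = ipar + 2.0 * iperp
    if np.any(denom <= 0):
        raise ValueError("I_parallel + 2*I_perpendicular must be positive")
    out = (ipar - iperp) / denom
    return float(out) if out.ndim == 0 else out


def intensities_from_anisotropy(r, total=3.0):
    """(I_par, I_perp) pair reproducing anisotropy r at fixed total I+2I."""
    r = np.asarray(r, float)
    ipar = total * (1.0 + 2.0 * r) / 3.0
    iperp = total * (1.0 - r) / 3.0
    return ipar, iperp


def hill_model(x, r_f, r_b, K_D, n, form: str = "sum"):
    """Hill isotherm; `form="product"` gives the literal r_f * (...) variant."""
    x = np.asarray(x, float)
    frac = np.zeros_like(x)
    pos = x > 0
    frac[pos] = x[pos] ** n / (K_D ** n + x[pos] ** n)
    if form == "sum":
        return r_f + r_b * frac
    if form == "product":
        return r_f * r_b * frac
    raise ValueError(f"unknown model form {form!r}")


def fit_hill(curve: TitrationCurve, form: str = "sum",
             n_min_points: int = 5) -> HillFit:
    """Bounded nonlinear least squares of the Hill isotherm, multi-start.

    Starts place K_D at the half-rise concentration scaled by {0.3, 1, 3}
    crossed with n in {1, 2, 4}; the lowest-RSS solution wins.  A fit is
    flagged unreliable (converged=False) when no start succeeds or the K_D
    variance exceeds K_D^2 (unidentifiable design, e.g. no upper plateau).
    """
    x, y = curve.concentrations, curve.r
    if len(x) < n_min_points:
        raise ValueError(f"need >= {n_min_points} titration points")

    rise = y - y.min()
    half = y.min() + 0.5 * rise.max()
    above = x[y >= half]
    kd_guess = float(above.min()) if len(above) and above.min() > 0 \
        else float(np.median(x[x > 0]))

    lb = [BOUNDS["r_f"][0], BOUNDS["r_b"][0], BOUNDS["K_D"][0], BOUNDS["n"][0]]
    ub = [BOUNDS["r_f"][1], BOUNDS["r_b"][1], BOUNDS["K_D"][1], BOUNDS["n"][1]]

    best = None
    for kd_scale in (0.3, 1.0, 3.0):
        for n0 in (1.0, 2.0, 4.0):
            p0 = [max(y.min(), 1e-4), max(rise.max(), 1e-4),
                  np.clip(kd_guess * kd_scale, lb[2], ub[2]), n0]
            try:
                popt, pcov = optimize.curve_fit(
                    lambda xx, rf, rb, kd, nn: hill_model(xx, rf, rb, kd, nn,
                                                          form=form),
                    x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((y - hill_model(x, *popt, form=form)) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)

    if best is None:
        return HillFit(K_D=np.nan, n=np.nan, r_f=np.nan, r_b=np.nan,
                       var_KD=np.nan, var_n=np.nan, converged=False)
    popt, pcov, rss = best
    r_f, r_b, K_D, n = (float(v) for v in popt)
    var_KD = float(pcov[2, 2])
    var_n = float(pcov[3, 3])
    at_bound = (K_D < 1.01 * BOUNDS["K_D"][0] or K_D > 0.99 * BOUNDS["K_D"][1]
                or n < 1.01 * BOUNDS["n"][0] or n > 0.99 * BOUNDS["n"][1])
    ok = (np.isfinite(var_KD) and np.isfinite(var_n)
          and var_KD < K_D ** 2 and var_n < n ** 2 and not at_bound)
    return HillFit(K_D=K_D, n=n, r_f=r_f, r_b=r_b,
                   var_KD=var_KD, var_n=var_n, converged=bool(ok), rss=rss)


def weighted_combine(estimates, variances) -> WeightedEstimate:
    """Inverse-variance weighted mean and standard error across replicates.

    x_wtd = sum(x_i / s_i^2) / sum(1 / s_i^2);
    se_wtd = sqrt([ (sum(x_i^2/s_i^2)/sum(1/s_i^2) - x_wtd^2) * m/(m-1) ] / m).
    A single replicate yields an undefined (NaN) standard error.
    """
    x = np.asarray(estimates, float)
    s2 = np.asarray(variances, float)
    if x.shape != s2.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("estimates and variances must be equal-length 1-D")
    if np.any(s2 <= 0):
        raise ValueError("variances must be strictly positive")
    m = len(x)
    w = 1.0 / s2
    x_wtd = float(np.sum(x * w) / np.sum(w))
    if m == 1:
        return WeightedEstimate(x_wtd=x_wtd, se_wtd=np.nan, m=1)
    second = float(np.sum(x ** 2 * w) / np.sum(w))
    var_wtd = max(second - x_wtd ** 2, 0.0) * (m / (m - 1.0)) / m
    return WeightedEstimate(x_wtd=x_wtd, se_wtd=float(np.sqrt(var_wtd)), m=m)


def fit_titration_table(frame: pd.DataFrame, form: str = "sum") -> pd.DataFrame:
    """Fit every (sequence, UV condition) in a long-format titration table.

    Expects columns sequence_id, replicate, uv, concentration_nM and either
    r or the intensity pair (I_par, I_perp).  Returns one row per condition
    with the weighted K_D and n estimates alongside replicate counts.
    """
    frame = frame.copy()
    if "r" not in frame.columns:
        if not {"I_par", "I_perp"} <= set(frame.columns):
            raise ValueError("need column 'r' or columns 'I_par'/'I_perp'")
        frame["r"] = anisotropy_from_intensities(frame["I_par"],
                                                 frame["I_perp"])
    rows = []
    for (seq, uv), grp in frame.groupby(["sequence_id", "uv"]):
        fits = []
        for rep, sub in grp.groupby("replicate"):
            sub = sub.sort_values("concentration_nM")
            curve = TitrationCurve(sequence_id=str(seq),
                                   concentrations=sub["concentration_nM"],
                                   r=sub["r"], replicate_id=str(rep),
                                   uv_treated=bool(uv))
            fit = fit_hill(curve, form=form)
            if fit.converged:
                fits.append(fit)
        if not fits:
            rows.append({"sequence_id": seq, "uv": uv, "m": 0,
                         "K_D": np.nan, "K_D_se": np.nan,
                         "n": np.nan, "n_se": np.nan})
            continue
        kd = weighted_combine([f.K_D for f in fits],
                              [f.var_KD for f in fits])
        nn = weighted_combine([f.n for f in fits],
                              [f.var_n for f in fits])
        rows.append({"sequence_id": seq, "uv": uv, "m": kd.m,
                     "K_D": kd.x_wtd, "K_D_se": kd.se_wtd,
                     "n": nn.x_wtd, "n_se": nn.se_wtd})
    return pd.DataFrame(rows)
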