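"""Spot-level array fluorescence to control-calibrated per-probe z-scores.

A chamber is one compartment of a multi-chamber binding array: every probe is
printed as ~10 replicate spots, fluorescence reports protein occupancy, and a
set of known low-affinity control sequences provides the null against which
specificity is measured.  The pipeline is

    parse_chamber -> spatial_detrend -> aggregate_replicates
        -> fit_control_null (on control probes) -> compute_zscores

Z-scores are (median fluorescence - mu) / sigma with (mu, sigma) from a
Gaussian fit to the kernel density estimate of control-probe medians, so a
z of 0 means "indistinguishable from a low-affinity sequence".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

__all__ = [
    "ChamberTable",
    "ProbeSummaries",
    "GaussianNull",
    "ProbeZScores",
    "parse_chamber",
    "spatial_detrend",
    "aggregate_replicates",
    "fit_control_null",
    "compute_zscores",
    "chamber_to_zscores",
]

SPOT_COLUMNS = ["probe_id", "replicate_index", "grid_x", "grid_y",
                "raw_intensity", "flagged"]


@dataclass
class ChamberTable:
    """Spot-level fluorescence for one chamber plus its condition."""

    chamber_id: str
    spots: pd.DataFrame  # columns SPOT_COLUMNS
    control_ids: frozenset[str] = frozenset()
    tfam_conc: float = np.nan  # nM
    uv_dose: float = np.nan  # J/m^2

    def __post_init__(self) -> None:
        missing = set(SPOT_COLUMNS) - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns: {sorted(missing)}")


@dataclass
class ProbeSummaries:
    """Per-probe replicate statistics (unflagged spots only)."""

    chamber_id: str
    table: pd.DataFrame  # index probe_id; n_used, mean, median, sd, sem

    def valid(self) -> pd.DataFrame:
        return self.table[self.table["n_used"] > 0]


@dataclass
class GaussianNull:
    mu: float
    sigma: float
    n_controls: int
    fit_rmse: float = np.nan
    robust_mu: float = np.nan  # median of control medians (diagnostic)
    robust_sigma: float = np.nan  # 1.4826 * MAD (diagnostic)

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"null sigma must be positive, got {self.sigma}")


@dataclass
class ProbeZScores:
    chamber_id: str
    z: pd.Series  # index probe_id
    null: GaussianNull


def parse_chamber(path, chamber_id: str = None, control_ids=(),
                  tfam_conc: float = np.nan,
                  uv_dose: float = np.nan) -> ChamberTable:
    """Read a tab-delimited chamber file (GPR dialect or plain TSV).

    The plain dialect carries the spot columns directly.  The GPR (GenePix
    results) dialect is detected by its ``Block``/``Column``/``Row`` header:
    ``ID`` maps to probe_id, ``F532 Median`` (or the first ``F* Median``
    column) to raw_intensity, and spots with ``Flags`` < 0 are marked flagged.
    Flagged rows are retained, not dropped.
    """
    path = str(path)
    # GPR files open with header lines ("ATF", counts) before the table.
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("ATF"):
        with open(path) as fh:
            fh.readline()
            n_header = int(fh.readline().split()[0])
        skip = 2 + n_header
    frame = pd.read_csv(path, sep="\t", skiprows=skip)

    if {"Block", "Column", "Row"} <= set(frame.columns):
        intensity_cols = [c for c in frame.columns
                          if c.startswith("F") and c.endswith("Median")]
        if not intensity_cols:
            raise ValueError("GPR file missing an 'F... Median' intensity column")
        if "ID" not in frame.columns:
            raise ValueError("GPR file missing required column 'ID'")
        spots = pd.DataFrame({
            "probe_id": frame["ID"].astype(str),
            "grid_x": frame["Column"].astype(int),
            "grid_y": frame["Row"].astype(int),
            "raw_intensity": frame[intensity_cols[0]].astype(float),
            "flagged": (frame["Flags"] < 0) if "Flags" in frame.columns
                       else False,
        })
        spots["replicate_index"] = spots.groupby("probe_id").cumcount() + 1
    else:
        missing = set(SPOT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"chamber file missing columns: {sorted(missing)}")
        spots = frame[SPOT_COLUMNS].copy()
        spots["flagged"] = spots["flagged"].astype(bool)

    dupes = spots.duplicated(subset=["probe_id", "replicate_index"])
    if dupes.any():
        dup = spots.loc[dupes, ["probe_id", "replicate_index"]].iloc[0]
        raise ValueError(
            f"duplicate spot for probe {dup['probe_id']!r} "
            f"replicate {dup['replicate_index']}"
        )
    spots = spots[SPOT_COLUMNS].reset_index(drop=True)
    return ChamberTable(
        chamber_id=chamber_id or path,
        spots=spots,
        control_ids=frozenset(control_ids),
        tfam_conc=tfam_conc,
        uv_dose=uv_dose,
    )


def _trend_surface(x, y, logint, n_bins: int, bandwidth_frac: float):
    """Smooth spatial trend of log-intensity, evaluated at each spot.

    Binned medians on an n_bins x n_bins grid are smoothed with a Gaussian
    kernel whose width is `bandwidth_frac` of the slide extent (local
    regression in spirit; the contract is flat control residuals, not a
    particular smoother).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xe = np.linspace(x.min(), x.max(), n_bins + 1)
    ye = np.linspace(y.min(), y.max(), n_bins + 1)
    xi = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, n_bins - 1)
    yi = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, n_bins - 1)
    flat = xi * n_bins + yi
    med = pd.Series(logint).groupby(flat).median()
    grid = np.full(n_bins * n_bins, np.nan)
    grid[med.index.to_numpy()] = med.to_numpy()
    grid = grid.reshape(n_bins, n_bins)
    if np.isnan(grid).any():  # fill empty bins before smoothing
        overall = np.nanmedian(grid)
        grid = np.where(np.isnan(grid), overall, grid)
    sigma = max(bandwidth_frac * n_bins, 0.75)
    smooth = ndimage.gaussian_filter(grid, sigma=sigma, mode="nearest")
    return smooth[xi, yi]


def spatial_detrend(chamber: ChamberTable, n_bins: int = 24,
                    bandwidth_frac: float = 0.15,
                    log_domain: bool = True) -> ChamberTable:
    """Divide out a smooth multiplicative spatial trend across the slide.

    The trend is estimated from all spots (binned medians of log intensity,
    Gaussian-kernel smoothed with bandwidth ~15% of the slide extent) and
    removed multiplicatively around 1; intensities are then rescaled so the
    overall median matches its pre-detrend value.  With fewer than two
    distinct grid positions the chamber is returned unchanged with a warning.
    `log_domain=False` estimates the same surface on linear intensities.
    """
    spots = chamber.spots
    pos = spots[["grid_x", "grid_y"]].drop_duplicates()
    ok = ~spots["flagged"] & (spots["raw_intensity"] > 0)
    if len(pos) < 3 or ok.sum() < 10:
        warnings.warn("degenerate chamber geometry; detrending skipped")
        return chamber

    x = spots["grid_x"].to_numpy(float)
    y = spots["grid_y"].to_numpy(float)
    inten = spots["raw_intensity"].to_numpy(float)
    work = np.log(np.clip(inten, 1e-12, None)) if log_domain else inten
    surf = _trend_surface(x[ok], y[ok], work[ok], n_bins, bandwidth_frac)
    full = np.empty_like(work)
    full[:] = np.nan
    full[np.flatnonzero(ok)] = surf
    # spots excluded from the fit still get corrected via their bin
    if np.isnan(full).any():
        all_surf = _trend_surface(x, y, np.where(ok, work, np.nanmedian(work[ok])),
                                  n_bins, bandwidth_frac)
        full = np.where(np.isnan(full), all_surf, full)

    if log_domain:
        factor = np.exp(full - np.median(full[ok]))
    else:
        center = np.median(full[ok])
        if center == 0:
            warnings.warn("flat zero trend; detrending skipped")
            return chamber
        factor = full / center
    corrected = inten / factor
    scale = np.median(inten[ok]) / np.median(corrected[ok])
    corrected = corrected * scale

    new_spots = spots.copy()
    new_spots["raw_intensity"] = corrected
    return replace(chamber, spots=new_spots)


def aggregate_replicates(chamber: ChamberTable) -> ProbeSummaries:
    """Mean / median / sd / sem per probe over unflagged replicates.

    Sample (n-1) standard deviation; probes with no usable replicate are kept
    with n_used = 0 and NaN statistics so downstream stages can exclude them.
    """
    spots = chamber.spots
    used = spots[~spots["flagged"]]
    grp = used.groupby("probe_id")["raw_intensity"]
    table = pd.DataFrame({
        "n_used": grp.size(),
        "mean": grp.mean(),
        "median": grp.median(),
        "sd": grp.std(ddof=1),
    })
    table["sd"] = table["sd"].fillna(0.0)  # single-replicate probes: sd 0
    table["sem"] = table["sd"] / np.sqrt(table["n_used"])
    # probes entirely flagged still appear, with missing statistics
    all_ids = pd.Index(spots["probe_id"].unique(), name="probe_id")
    table = table.reindex(all_ids)
    table["n_used"] = table["n_used"].fillna(0).astype(int)
    return ProbeSummaries(chamber_id=chamber.chamber_id, table=table)


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_control_null(summaries: ProbeSummaries,
                     control_ids) -> GaussianNull:
    """Gaussian null from the KDE of control-probe medians.

    A Gaussian kernel density estimate (Silverman bandwidth) of the control
    medians is evaluated on a grid and a Gaussian curve is fit to it by least
    squares; the fitted (mu, sigma) parameterise the null.  A robust
    median/MAD estimate is kept as a diagnostic cross-check.
    """
    control_ids = set(control_ids)
    valid = summaries.valid()
    med = valid.loc[valid.index.isin(control_ids), "median"].dropna()
    if len(med) < 20:
        raise ValueError(
            f"need >= 20 control probes with valid medians, got {len(med)}")
    vals = med.to_numpy(float)
    if np.ptp(vals) == 0:
        raise ValueError("all control medians identical; null undefined")

    kde = stats.gaussian_kde(vals, bw_method="silverman")
    lo, hi = vals.min(), vals.max()
    pad = 0.5 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    p0 = (dens.max(), float(np.median(vals)), float(np.std(vals)))
    popt, _ = optimize.curve_fit(_gauss, grid, dens, p0=p0, maxfev=10000)
    amp, mu, sigma = popt
    sigma = abs(sigma)
    rmse = float(np.sqrt(np.mean((dens - _gauss(grid, *popt)) ** 2)))
    mad = stats.median_abs_deviation(vals, scale="normal")
    return GaussianNull(mu=float(mu), sigma=float(sigma),
                        n_controls=len(vals), fit_rmse=rmse,
                        robust_mu=float(np.median(vals)),
                        robust_sigma=float(mad))


def compute_zscores(summaries: ProbeSummaries,
                    null: GaussianNull) -> ProbeZScores:
    """z = (median - mu) / sigma per probe; controls included.

    Probes with no usable replicates get a missing z.
    """
    table = summaries.table
    z = (table["median"] - null.mu) / null.sigma
    z[table["n_used"] == 0] = np.nan
    z.name = "z"
    return ProbeZScores(chamber_id=summaries.chamber_id, z=z, null=null)


def chamber_to_zscores(chamber: ChamberTable, detrend: bool = True,
                       **detrend_kw) -> ProbeZScores:
    """Convenience: full chamber pipeline down to per-probe z-scores."""
    if not chamber.control_ids:
        raise ValueError("chamber has no control_ids; null cannot be fit")
    if detrend:
        chamber = spatial_detrend(chamber, **detrend_kw)
    summaries = aggregate_replicates(chamber)
    null = fit_control_null(summaries, chamber.control_ids)
    return compute_zscores(summaries, null)
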