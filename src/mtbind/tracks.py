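"""Genome-coordinate specificity tracks and UV specificity-loss statistics.

Per-probe z-scores from the two probe orientations are collapsed by taking
the larger of the two (orientation max), projected onto the genome at the
middle nucleotide of each window, and optionally smoothed with a circular
rolling mean matching the protein's ~22-nt footprint.  Tail partitions and
the change-in-z (delta-z) regression quantify how much sequence specificity
survives UV irradiation: under a pure specificity compression
z_UV = (1-gamma) * z_noUV, the regression of delta-z on baseline z has slope
-gamma, the top tail falls and the bottom tail rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .genome import ProbeLibrary

__all__ = [
    "ZTrack",
    "RegionSet",
    "split_orientations",
    "zscores_to_track",
    "orientation_max",
    "project_to_genome",
    "smooth_track",
    "percentile_partition",
    "delta_z_analysis",
    "motif_zscore_compare",
    "region_summary",
    "write_bedgraph",
    "read_regions_bed",
]


@dataclass
class ZTrack:
    """Binding-specificity values on genome coordinates (circular)."""

    genome_length: int
    coords: np.ndarray  # strictly increasing, 0-based
    values: np.ndarray
    stage: str = "per_orientation"  # per_orientation | orientation_max | smoothed

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, int)
        self.values = np.asarray(self.values, float)
        if self.coords.shape != self.values.shape:
            raise ValueError("coords and values must align")
        if np.any(np.diff(self.coords) <= 0):
            raise ValueError("coords must be strictly increasing")

    def mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class RegionSet:
    """Named 0-based half-open genomic intervals (may wrap the origin)."""

    genome_length: int
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (start, end) in self.regions.items():
            if not (0 <= start < self.genome_length
                    and 0 < end <= self.genome_length):
                raise ValueError(f"region {name!r} outside genome bounds")


def split_orientations(z: pd.Series, library: ProbeLibrary):
    """Per-probe z (indexed by probe_id) -> (z_forward, z_reverse) by start."""
    def pick(probes):
        ids = [p.probe_id for p in probes]
        starts = [p.start for p in probes]
        return pd.Series(z.reindex(ids).to_numpy(), index=starts).sort_index()

    return pick(library.forward_probes()), pick(library.reverse_probes())


def zscores_to_track(z: pd.Series, library: ProbeLibrary,
                     smooth_span: int | None = None) -> ZTrack:
    """Probe z-scores -> orientation-max genome track, optionally smoothed."""
    fwd, rev = split_orientations(z, library)
    track = project_to_genome(orientation_max(fwd, rev), library)
    if smooth_span is not None:
        track = smooth_track(track, span_nt=smooth_span)
    return track


def orientation_max(z_forward: pd.Series, z_reverse: pd.Series) -> pd.Series:
    """Per-window max of the two orientation z-scores.

    Inputs are indexed by window start.  A window missing one orientation
    keeps the other; missing both stays missing.  Mismatched window sets are
    an error (the library is malformed).
    """
    sym = z_forward.index.symmetric_difference(z_reverse.index)
    if len(sym):
        raise ValueError(
            f"orientations cover different windows, e.g. {list(sym[:5])}")
    both = pd.concat({"fwd": z_forward, "rev": z_reverse}, axis=1)
    out = both.max(axis=1, skipna=True)
    out[both.isna().all(axis=1)] = np.nan
    out.name = "z"
    return out.sort_index()


def project_to_genome(window_z: pd.Series, library: ProbeLibrary) -> ZTrack:
    """Place per-window values at the middle-nucleotide genome coordinate."""
    L = library.genome.length
    starts = np.asarray(window_z.index, int)
    coords = (starts + library.window // 2) % L
    if len(np.unique(coords)) != len(coords):
        raise ValueError("duplicate genome coordinates; library malformed")
    order = np.argsort(coords)
    return ZTrack(genome_length=L, coords=coords[order],
                  values=window_z.to_numpy(float)[order],
                  stage="orientation_max")


def smooth_track(track: ZTrack, span_nt: int = 22) -> ZTrack:
    """Centered circular rolling mean over coordinates within `span_nt`.

    At tiling step s the window holds the 2*floor((span/2)/s)+1 consecutive
    coordinates no farther than span/2 nt away (11 coordinates for the
    default 22-nt span at 2-nt step), wrapping across the origin.
    """
    steps = np.diff(track.coords)
    step = int(steps.min()) if len(steps) else 1
    if span_nt < step:
        import warnings
        warnings.warn("smoothing span below tiling step; returning track")
        return track
    k = 2 * ((span_nt // 2) // step) + 1
    vals = track.values
    if np.isnan(vals).any():
        filled = np.where(np.isnan(vals), np.nanmean(vals), vals)
    else:
        filled = vals
    smooth = ndimage.uniform_filter1d(filled, size=k, mode="wrap")
    return ZTrack(genome_length=track.genome_length, coords=track.coords,
                  values=smooth, stage="smoothed")


def percentile_partition(track: ZTrack, tail_fraction: float = 0.05):
    """Index arrays of the top and bottom z tails.

    Operates on the (unsmoothed) per-probe values; each set holds
    round(tail_fraction * n) members; ties break by genome coordinate
    ascending for determinism.  Returns (top_idx, bottom_idx) as positions
    into track.coords/track.values.
    """
    finite = np.flatnonzero(np.isfinite(track.values))
    if len(finite) < 40:
        raise ValueError("need >= 40 values for a tail partition")
    n_tail = int(round(tail_fraction * len(finite)))
    vals = track.values[finite]
    coords = track.coords[finite]
    bottom = finite[np.lexsort((coords, vals))[:n_tail]]
    top = finite[np.lexsort((coords, -vals))[:n_tail]]
    return np.sort(top), np.sort(bottom)


def delta_z_analysis(z_no_uv: ZTrack, z_uv: ZTrack,
                     tail_fraction: float = 0.05) -> dict:
    """Specificity-loss statistics from a matched -UV / +UV track pair.

    Reports the least-squares slope and Pearson/Spearman correlations of
    delta-z (= z_UV - z_noUV) against baseline z, and the median delta-z of
    the baseline top and bottom tails.  A compression of specificity shows as
    a negative slope with the top tail shifting down and the bottom tail up.
    """
    if z_no_uv.genome_length != z_uv.genome_length or \
            not np.array_equal(z_no_uv.coords, z_uv.coords):
        raise ValueError("tracks must share identical coordinates")
    base = z_no_uv.values
    delta = z_uv.values - base
    ok = np.isfinite(base) & np.isfinite(delta)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 shared finite coordinates")
    b, d = base[ok], delta[ok]

    slope, intercept = np.polyfit(b, d, 1)
    pearson = float(stats.pearsonr(b, d)[0]) if np.std(d) > 0 else 0.0
    spearman = float(stats.spearmanr(b, d)[0]) if np.std(d) > 0 else 0.0

    top, bottom = percentile_partition(z_no_uv, tail_fraction)
    top_delta = z_uv.values[top] - z_no_uv.values[top]
    bottom_delta = z_uv.values[bottom] - z_no_uv.values[bottom]
    return {
        "delta_slope": float(slope),
        "delta_intercept": float(intercept),
        "delta_corr_pearson": pearson,
        "delta_corr_spearman": spearman,
        "n": int(ok.sum()),
        "top_tail_median_delta": float(np.nanmedian(top_delta)),
        "bottom_tail_median_delta": float(np.nanmedian(bottom_delta)),
        "top_tail_median_z_no_uv": float(np.nanmedian(z_no_uv.values[top])),
        "top_tail_median_z_uv": float(np.nanmedian(z_uv.values[top])),
        "bottom_tail_median_z_no_uv": float(np.nanmedian(z_no_uv.values[bottom])),
        "bottom_tail_median_z_uv": float(np.nanmedian(z_uv.values[bottom])),
    }


def motif_zscore_compare(z: pd.Series, has_motif: pd.Series) -> dict:
    """Compare z distributions between motif-bearing and motif-free probes."""
    has_motif = has_motif.reindex(z.index)
    with_m = z[has_motif.fillna(False).astype(bool)].dropna()
    without_m = z[~has_motif.fillna(False).astype(bool)].dropna()
    for name, grp in (("with_motif", with_m), ("without_motif", without_m)):
        if grp.empty:
            raise ValueError(f"group {name} is empty")
    ks = stats.ks_2samp(with_m, without_m)
    return {
        "n_with": int(len(with_m)),
        "n_without": int(len(without_m)),
        "median_with": float(with_m.median()),
        "median_without": float(without_m.median()),
        "median_difference": float(with_m.median() - without_m.median()),
        "iqr_with": float(with_m.quantile(0.75) - with_m.quantile(0.25)),
        "iqr_without": float(without_m.quantile(0.75) - without_m.quantile(0.25)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def _in_region(coords: np.ndarray, start: int, end: int, L: int) -> np.ndarray:
    if start < end:
        return (coords >= start) & (coords < end)
    return (coords >= start) | (coords < end)  # wraps the origin


def region_summary(track: ZTrack, regions: RegionSet) -> pd.DataFrame:
    """Per-region mean, max and max coordinate; circular-aware intervals."""
    rows = []
    for name, (start, end) in regions.regions.items():
        mask = _in_region(track.coords, start, end, track.genome_length)
        mask &= np.isfinite(track.values)
        if not mask.any():
            rows.append({"region": name, "n": 0, "mean": np.nan,
                         "max": np.nan, "max_coord": -1})
            continue
        vals = track.values[mask]
        coords = track.coords[mask]
        imax = int(np.argmax(vals))
        rows.append({"region": name, "n": int(mask.sum()),
                     "mean": float(vals.mean()), "max": float(vals.max()),
                     "max_coord": int(coords[imax])})
    return pd.DataFrame(rows).set_index("region")


# ---------------------------------------------------------------------------
# IO

def write_bedgraph(track: ZTrack, path: str | Path,
                   chrom: str = "chrM") -> None:
    """bedGraph export (0-based half-open, one record per coordinate)."""
    ok = np.isfinite(track.values)
    frame = pd.DataFrame({
        "chrom": chrom,
        "start": track.coords[ok],
        "end": track.coords[ok] + 1,
        "value": track.values[ok],
    })
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path: str | Path, genome_length: int) -> RegionSet:
    """Read named intervals from a BED file (chrom, start, end, name)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        usecols=[0, 1, 2, 3],
                        names=["chrom", "start", "end", "name"])
    regions = {str(r["name"]): (int(r["start"]), int(r["end"]))
               for _, r in frame.iterrows()}
    if len(regions) != len(frame):
        raise ValueError("region names must be unique")
    return RegionSet(genome_length=genome_length, regions=regions)
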