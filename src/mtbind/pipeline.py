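"""End-to-end convenience drivers tying the stages together."""

from __future__ import annotations

import pandas as pd

from .arrays import ChamberTable, chamber_to_zscores
from .genome import ProbeLibrary
from .tracks import delta_z_analysis, zscores_to_track

__all__ = ["uv_specificity_analysis"]


def uv_specificity_analysis(library: ProbeLibrary, no_uv: ChamberTable,
                            uv: ChamberTable, detrend: bool = True,
                            tail_fraction: float = 0.05) -> dict:
    """Chamber pair -> per-probe z-scores -> delta-z specificity-loss report.

    Each chamber is normalised against its own control null; tracks are the
    orientation-max per-probe z on genome coordinates (unsmoothed, as the
    tail and delta-z statistics are probe-level).
    """
    z_no = chamber_to_zscores(no_uv, detrend=detrend)
    z_uv = chamber_to_zscores(uv, detrend=detrend)
    probe_ids = pd.Index([p.probe_id for p in library.probes])
    track_no = zscores_to_track(z_no.z.reindex(probe_ids), library)
    track_uv = zscores_to_track(z_uv.z.reindex(probe_ids), library)
    report = delta_z_analysis(track_no, track_uv, tail_fraction=tail_fraction)
    return {
        "zscores": (z_no, z_uv),
        "tracks": (track_no, track_uv),
        "report": report,
    }
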