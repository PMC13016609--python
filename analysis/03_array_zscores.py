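#!/usr/bin/env python
"""Normalize the simulated chambers into per-probe binding z-scores.

Reads the GPR-dialect chamber files from step 02, removes the spatial
intensity trend, aggregates the replicate spots, fits the Gaussian null to
the kernel density estimate of the 116 control medians, and converts probe
medians to z-scores.  Each chamber is calibrated against its own null.

Writes results/zscores_noUV.tsv and results/zscores_UV.tsv.
"""

import sys
from pathlib import Path

import mtbind as m

OUT = Path(__file__).resolve().parents[1] / "results"


def main(_seed: int = 1) -> None:
    controls = [l.strip() for l in
                (OUT / "controls.txt").read_text().splitlines() if l.strip()]
    for label in ("noUV", "UV"):
        chamber = m.parse_chamber(OUT / f"chamber_{label}.gpr",
                                  chamber_id=label, control_ids=controls)
        detrended = m.spatial_detrend(chamber)
        summaries = m.aggregate_replicates(detrended)
        null = m.fit_control_null(summaries, chamber.control_ids)
        scores = m.compute_zscores(summaries, null)
        frame = summaries.table.join(scores.z).reset_index()
        frame[["probe_id", "n_used", "median", "z"]].to_csv(
            OUT / f"zscores_{label}.tsv", sep="\t", index=False)
        print(f"{label}: null mu={null.mu:.1f} sigma={null.sigma:.2f} "
              f"(robust {null.robust_mu:.1f}/{null.robust_sigma:.2f}, "
              f"{null.n_controls} controls); "
              f"{int((frame['n_used'] > 0).sum())} probes scored")
    print(f"wrote {OUT / 'zscores_noUV.tsv'} and {OUT / 'zscores_UV.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
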