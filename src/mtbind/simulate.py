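"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study conditions end to end: a circular genome
(default 16,569 nt at mitochondrial base composition), a two-orientation
tiling library, chamber pairs with 10 replicate spots per probe and 116
low-affinity control sequences, a smooth multiplicative spatial trend,
lognormal replicate noise, Hill-model anisotropy titrations and
Poisson-lesion qPCR amplification series.

The UV effect on the binding landscape is modelled as an affine specificity
compression toward a uniform uplift: occupancy' = (1-gamma)*occupancy +
gamma*b.  This is the minimal model that reproduces both observed tail
shifts (top z-scores fall, bottom z-scores rise after irradiation) and makes
the delta-z regression slope identifiable as -gamma; no mechanistic fidelity
is claimed.

All generators are deterministic given (seed, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import ChamberTable, SPOT_COLUMNS
from .genome import (CircularGenome, ProbeLibrary, annotate_gn10g,
                     sanitize_genome, tile_circular_genome)
from .lesions import LesionCalibration, QpcrMeasurement, expected_lesions
from .anisotropy import TitrationCurve, hill_model, intensities_from_anisotropy

__all__ = [
    "SimulationConfig",
    "TrueLandscape",
    "simulate_genome",
    "simulate_landscape",
    "simulate_chamber_pair",
    "simulate_titration",
    "simulate_qpcr_run",
    "write_chamber_gpr",
]


@dataclass
class SimulationConfig:
    """Study-condition defaults for every generator.

    Counts and conditions mirror the assay: 16,569-nt circular genome,
    33-nt/2-nt tiling, 10 replicate spots, 116 controls, 30 nM protein,
    0 vs 1500 J/m^2 chambers.  Noise scales are chosen at realistic assay
    magnitudes: 10% replicate CV, a +/-50% multiplicative spatial trend
    across the slide, 0.002 anisotropy noise, 5% qPCR CV.
    """

    seed: int = 0
    genome_length: int = 16569
    gc_fraction: float = 0.44  # human mtDNA GC content
    window: int = 33
    step: int = 2
    n_controls: int = 116
    replicates: int = 10
    control_mu: float = 500.0
    control_sigma: float = 50.0
    occupancy_high_fraction: float = 0.05
    z_high: float = 4.0
    uv_gamma: float = 0.5
    uv_uplift: float = 0.5  # the uniform baseline occupancy gained under UV
    spatial_trend_amplitude: float = 0.5
    noise_cv: float = 0.1
    titration_noise_sd: float = 0.002
    qpcr_noise_cv: float = 0.05
    tfam_conc: float = 30.0
    uv_dose: float = 1500.0


@dataclass
class TrueLandscape:
    """Ground-truth per-window occupancy (z-scale) and motif flags."""

    starts: np.ndarray
    occupancy: np.ndarray
    has_motif: np.ndarray
    high_mask: np.ndarray


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def simulate_genome(config: SimulationConfig) -> CircularGenome:
    """I.i.d. bases at the configured GC fraction; seed-deterministic."""
    rng = _rng(config, 1)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = rng.choice(np.array(list("ACGT")), size=config.genome_length,
                       p=probs)
    return sanitize_genome("".join(bases), name="sim_genome")


def simulate_landscape(library: ProbeLibrary,
                       config: SimulationConfig) -> TrueLandscape:
    """Plant high-occupancy windows independent of motif content.

    A fraction `occupancy_high_fraction` of windows gets occupancy
    ~N(z_high, 0.5); the rest ~N(0, 1).  Motif flags come from the forward
    probe sequence, so motif status and occupancy are independent by
    construction.
    """
    rng = _rng(config, 2)
    fwd = library.forward_probes()
    starts = np.array([p.start for p in fwd])
    n = len(fwd)
    high = rng.random(n) < config.occupancy_high_fraction
    occ = rng.normal(0.0, 1.0, size=n)
    occ[high] = rng.normal(config.z_high, 0.5, size=int(high.sum()))
    motif = np.array([annotate_gn10g(p).has_gn10g for p in fwd])
    return TrueLandscape(starts=starts, occupancy=occ, has_motif=motif,
                         high_mask=high)


def _lognormal_factor(rng, cv, size):
    if cv <= 0:
        return np.ones(size)
    s2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=size)


def _control_ids(config: SimulationConfig) -> list[str]:
    return [f"ctrl{i:03d}" for i in range(config.n_controls)]


def simulate_chamber_pair(library: ProbeLibrary, landscape: TrueLandscape,
                          config: SimulationConfig):
    """Matched (-UV, +UV) chambers from one binding landscape.

    Expected spot intensity is control_mu + control_sigma * occupancy', with
    occupancy' = occupancy in the -UV chamber and
    (1-gamma)*occupancy + gamma*uplift in the +UV chamber; both probe
    orientations of a window share its occupancy.  Controls sit at occupancy
    0.  Spots are laid out on a square grid in shuffled order, a smooth
    multiplicative trend (range 1 +/- amplitude across the slide) is applied,
    and each replicate gets lognormal noise at the configured CV.
    """
    occ_by_start = dict(zip(landscape.starts, landscape.occupancy))
    probe_ids = [p.probe_id for p in library.probes]
    probe_occ = np.array([occ_by_start[p.start] for p in library.probes])
    ctrl_ids = _control_ids(config)

    ids = np.array(probe_ids + ctrl_ids)
    occ = np.concatenate([probe_occ, np.zeros(len(ctrl_ids))])

    chambers = []
    for salt, (label, uv_dose) in enumerate(
            [("noUV", 0.0), ("UV", config.uv_dose)]):
        rng = _rng(config, 10 + salt)
        if uv_dose > 0:
            occ_eff = (1 - config.uv_gamma) * occ \
                + config.uv_gamma * config.uv_uplift
        else:
            occ_eff = occ
        expected = config.control_mu + config.control_sigma * occ_eff

        n_spots = len(ids) * config.replicates
        spot_ids = np.repeat(ids, config.replicates)
        spot_expected = np.repeat(expected, config.replicates)
        rep_index = np.tile(np.arange(1, config.replicates + 1), len(ids))

        side = int(np.ceil(np.sqrt(n_spots)))
        order = rng.permutation(n_spots)
        gx = order % side
        gy = order // side
        u = (gx / side + gy / side) / 2.0  # smooth diagonal gradient
        trend = 1.0 + config.spatial_trend_amplitude * (2.0 * u - 1.0)

        noise = _lognormal_factor(rng, config.noise_cv, n_spots)
        intensity = spot_expected * trend * noise

        spots = pd.DataFrame({
            "probe_id": spot_ids,
            "replicate_index": rep_index,
            "grid_x": gx,
            "grid_y": gy,
            "raw_intensity": intensity,
            "flagged": False,
        })[SPOT_COLUMNS]
        chambers.append(ChamberTable(
            chamber_id=f"sim_{label}",
            spots=spots,
            control_ids=frozenset(ctrl_ids),
            tfam_conc=config.tfam_conc,
            uv_dose=uv_dose,
        ))
    return chambers[0], chambers[1]


def simulate_titration(K_D: float, n: float, r_f: float = 0.05,
                       r_b: float = 0.15, concentrations=None,
                       noise_sd: float = 0.002, replicates: int = 3,
                       seed: int = 0, sequence_id: str = "seq",
                       uv_treated: bool = False,
                       emit_intensities: bool = False):
    """Hill-model titration replicates with Gaussian anisotropy noise.

    Default concentrations are 12 points spanning 0-15 nM (zero plus a
    half-log dilution ladder), matching the assay design.  With
    `emit_intensities` each curve also carries (I_par, I_perp) pairs exactly
    consistent with its r values.
    """
    if concentrations is None:
        # zero plus an 11-step serial dilution down from 15 nM
        concentrations = np.concatenate(
            [[0.0], np.sort(15.0 / 1.5 ** np.arange(11))])
    concentrations = np.asarray(concentrations, float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    truth = hill_model(concentrations, r_f, r_b, K_D, n)
    curves = []
    for i in range(replicates):
        r = truth + rng.normal(0.0, noise_sd, size=len(concentrations))
        curve = TitrationCurve(sequence_id=sequence_id,
                               concentrations=concentrations, r=r,
                               replicate_id=f"rep{i + 1}",
                               uv_treated=uv_treated)
        if emit_intensities:
            curve.I_par, curve.I_perp = intensities_from_anisotropy(r)
        curves.append(curve)
    return curves


def simulate_qpcr_run(doses, amplicon_kb: float = 10.0,
                      calib: LesionCalibration = LesionCalibration(),
                      true_copy_ratio: float = 1.0,
                      noise_cv: float = 0.05, seed: int = 0):
    """qPCR measurements across a UVC dose series.

    Long amplification is exp(-lambda(dose)) times shared copy-number and
    residual lognormal noise; the short products carry the copy factor and
    the true mito:nuclear ratio, so short-normalisation cancels copy-number
    variability as in the real assay.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    out = []
    for i, dose in enumerate(np.asarray(doses, float)):
        lam = expected_lesions(dose, amplicon_kb, calib)
        copy_factor = float(_lognormal_factor(rng, noise_cv, 1)[0])
        long_noise = float(_lognormal_factor(rng, noise_cv, 1)[0])
        short_noise = float(_lognormal_factor(rng, noise_cv, 1)[0])
        nuclear_noise = float(_lognormal_factor(rng, noise_cv, 1)[0])
        out.append(QpcrMeasurement(
            sample_id=f"dose{dose:g}_{i}",
            dose=float(dose),
            long_amplification=np.exp(-lam) * copy_factor * long_noise,
            short_amplification_mito=copy_factor * short_noise,
            short_amplification_nuclear=copy_factor * nuclear_noise
            / true_copy_ratio,
            long_amplicon_kb=amplicon_kb,
        ))
    return out


# ---------------------------------------------------------------------------
# File emission (GPR dialect + truth JSON) for round-trip testing and the CLI

def write_chamber_gpr(chamber: ChamberTable, path: str | Path) -> None:
    """Write a chamber as a minimal GenePix-results-dialect text file."""
    header = ["ATF\t1.0", "2\t6",
              f'"ChamberID={chamber.chamber_id}"',
              f'"TFAMConc={chamber.tfam_conc}"']
    frame = pd.DataFrame({
        "Block": 1,
        "Column": chamber.spots["grid_x"],
        "Row": chamber.spots["grid_y"],
        "Name": chamber.spots["probe_id"],
        "ID": chamber.spots["probe_id"],
        "F532 Median": chamber.spots["raw_intensity"],
        "Flags": np.where(chamber.spots["flagged"], -100, 0),
    })
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_truth_json(landscape: TrueLandscape, config: SimulationConfig,
                     path: str | Path) -> None:
    payload = {
        "config": asdict(config),
        "starts": landscape.starts.tolist(),
        "occupancy": landscape.occupancy.tolist(),
        "has_motif": landscape.has_motif.astype(bool).tolist(),
        "high_mask": landscape.high_mask.astype(bool).tolist(),
    }
    Path(path).write_text(json.dumps(payload))
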