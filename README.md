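# mtbind

Quantitative machinery for analysing how a DNA-packaging protein's sequence
specificity across a circular genome changes when the DNA carries UV
photolesions. The package targets the workflow of high-density protein-DNA
binding arrays tiled over the human mitochondrial genome and the companion
biochemical assays, built around TFAM (mitochondrial transcription factor A)
as the protein of interest:

- **Probe design** — partition a circular genome into overlapping windows
  (33 nt, shifted 2 nt per probe, wrapping the origin) synthesised in both
  orientations; annotate windows for the proposed minimal recognition motif
  GN₁₀G and for dipyrimidine (UV-target) density.
- **Array normalisation** — spot fluorescence → spatial detrending →
  replicate aggregation → binding z-scores calibrated against a Gaussian
  null fitted to the kernel density estimate of 116 low-affinity control
  sequences: `z = (median − μ)/σ`.
- **Genome tracks** — per-window orientation max, projection to the middle
  nucleotide, circular 22-nt smoothing (the protein's footprint); top/bottom
  5% tail partitions; the specificity-loss regression of Δz = z₊UV − z₋UV on
  baseline z, whose slope estimates −γ under an affine compression
  z₊UV = (1−γ)·z₋UV + const.
- **Anisotropy fits** — r = (I∥ − I⊥)/(I∥ + 2I⊥), Hill isotherm
  r(x) = r_f + r_b·xⁿ/(K_Dⁿ + xⁿ), and inverse-variance weighted
  combination of replicate estimates (with the m/(m−1) small-sample factor
  in the weighted standard error).
- **Damage model** — linear UVC dose→photolesion expectation
  (λ = rate·dose·length, default rate 0.01 lesions·kb⁻¹·(J/m²)⁻¹), the
  Poisson zero class exp(−λ), and inversion of long-amplicon qPCR relative
  amplification into lesions per 10 kb with short-product copy-number
  normalisation.
- **Synthetic data** — seed-deterministic generators for every input
  (genome, landscape, chamber spot tables in GPR dialect, titrations, qPCR
  series), so the full pipeline is exercised without any external download.

## Worked example

The numbered scripts under `analysis/` run the whole study-scale workflow on
synthetic data and write their tables under `results/`:

```sh
python analysis/01_design_library.py 1
python analysis/02_simulate_chambers.py 1
python analysis/03_array_zscores.py
python analysis/04_uv_specificity.py
python analysis/05_anisotropy_fits.py 1
python analysis/06_damage_model.py 1
```

Step 01 prints the library geometry for a 16,569-nt circular genome:

```
probes: 8285 per orientation, 16570 total (window 33, step 2)
```

— every genome position covered by 16–17 forward probes. Steps 02–04 plant
a sparse high-occupancy landscape (5% of windows at z ≈ 4), render a
−UV / +UV chamber pair with a γ = 0.5 specificity compression, and recover
it through the full normalisation:

```
noUV: null mu=495.7 sigma=19.32 (116 controls); 16686 probes scored
delta-z slope: -0.625 (Pearson r -0.946, Spearman -0.928)
top-5% median z: 10.83 -> 4.74; bottom-5%: -4.85 -> -1.45
GN10G vs non-motif: median z difference -0.058 (KS 0.026)
```

The negative slope and the opposite tail shifts are the specificity-loss
signature: strong binders lose z after UV, weak binders gain. A single
chamber pair estimates the slope with scatter of roughly ±0.05 (the null σ
rests on 116 controls), so a one-seed value like −0.625 sits within the
sampling band around −γ − a small attenuation bias; averaging seeds
recovers −0.5 (see `tests/test_acceptance.py`). The motif comparison is
correctly null: the generator plants occupancy independent of GN₁₀G
content. Step 05 fits triplicate anisotropy titrations generated at
published binding parameters:

```
ND4_473:  K_D = 4.99 +/- 0.03 nM (generated at 4.95), n = 5.03 +/- 0.06 (generated at 5.06)
COX2_229: K_D = 3.95 +/- 0.02 nM (generated at 3.94), n = 2.81 +/- 0.05 (generated at 2.77)
```

and step 06 inverts a qPCR dose series back into lesion frequencies
(`10 J/m² → 1.005 lesions/10 kb`, fitted rate `0.0100 per kb per J/m²`).

The same functionality is exposed as a CLI (`mtbind design / normalize /
tracks / compare / anisofit / lesions / simulate`) for use on real scanner
exports; see `mtbind --help`.

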