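# Methods

## Problem setting

TFAM coats and compacts the ~16.6-kb circular mitochondrial genome and
initiates transcription at its promoters. High-density binding arrays
measure its relative occupancy on thousands of short double-stranded
probes simultaneously; comparing an untreated chamber with a UVC-irradiated
one asks whether photolesions change *where* the protein prefers to bind.
This package implements the quantitative steps of that comparison plus the
two companion assays (fluorescence-anisotropy titrations and long-amplicon
qPCR damage quantification), and a generator that produces statistically
faithful synthetic inputs for all of them.

## Probe design

A circular genome of length L is tiled with windows of width w = 33 nt
shifted s = 2 nt per probe, starting at offset 0 and wrapping across the
origin, giving ceil(L/s) probes per orientation (8,285 for L = 16,569; a
reverse-complement probe is emitted per window, 16,570 total). Each probe
carries the window plus a constant 27-nt primer-binding sequence; the
primer on physical arrays is proprietary to the design, so the package
ships an arbitrary fixed 27-mer as a configurable default — it never
enters genome-coordinate logic. Coordinates are 0-based half-open
internally; BED/bedGraph exports follow their conventions. A probe is
keyed to the genome at the middle nucleotide of its variable region,
`(start + w//2) mod L`.

Ambiguity handling: an `N` in the reference is replaced by `C` before
tiling (the mitochondrial reference contains a single placeholder `N`);
any other non-ACGT character is rejected with its position.

The GN₁₀G motif (two guanines separated by ten arbitrary nucleotides) is
searched on both strands of the variable region — double-stranded probes
present both — by scanning the given strand for `G·N₁₀·G` and `C·N₁₀·C`
(the latter is the motif on the complement), reporting all overlapping
match offsets.

Dipyrimidine density counts dinucleotides that are pyrimidine–pyrimidine
on either strand of the duplex (YY on the given strand, or RR, which reads
YY on the complement), per kb, including the junction dinucleotide for
circular sequences. Single-strand counting cannot reach the published
~510–535/kb magnitudes for plasmid and mitochondrial sequences, so the
both-strand convention is adopted; under it, an i.i.d. sequence at
mitochondrial base composition (pyrimidine fraction ≈ 0.56) gives
(p_Y² + p_R²)·1000 ≈ 507/kb, bracketing those published values. The exact
reference sequences are deliberately not bundled; the tests validate the
convention on hand-countable duplexes, the strand-symmetry property, and
composition-matched synthetic sequences.

## Array normalisation

Each chamber is processed independently:

1. **Detrending.** A smooth multiplicative intensity trend across the
   slide is estimated from all unflagged spots — binned medians of
   log-intensity on a 24×24 grid, smoothed with a Gaussian kernel of width
   15% of the slide extent — divided out, and the overall median restored.
   The contract is what is tested (a constant field passes through
   unchanged; a 0.5→1.5 gradient leaves control-spot CV reduced at least
   five-fold), not the smoother's internals. Whether the surface is fit on
   log or linear intensities is a switch (`log_domain`, default log).
   Degenerate geometry (fewer than three distinct positions) falls back to
   the identity with a warning.
2. **Replicate aggregation.** Mean, median, sample (n−1) SD and SEM per
   probe over unflagged replicates only; probes with no usable replicate
   are kept with n_used = 0 and missing statistics. Flags are preserved in
   files, never imputed.
3. **Null calibration.** A Gaussian kernel density estimate (Silverman
   bandwidth) of the control-probe medians is evaluated on a 512-point
   grid and a Gaussian is fit to the curve by least squares; the fitted
   (μ, σ) define the null. Fitting a Gaussian to a KDE rather than to the
   samples inflates σ by roughly √(1 + h²/σ²) (~8% at n = 116); this is
   inherent to the method and left uncorrected. A robust median/MAD
   estimate is carried as a diagnostic. At least 20 valid controls are
   required; identical controls are an error.
4. **Z-scores.** z = (median − μ)/σ, controls included. Medians (not
   means) feed the transform.

The z-transform is affine-invariant: rescaling all intensities and
refitting the null leaves z unchanged.

## Genome tracks and the UV specificity-loss statistic

Per window, the larger z of the two orientations is taken (a missing
orientation falls back to the other), projected to the middle-nucleotide
coordinate, and — for track export only — smoothed with a centred circular
rolling mean spanning 22 nt (11 consecutive coordinates at 2-nt tiling),
matching the protein's ~22-nt footprint. Smoothing preserves the circular
mean and commutes with genome rotation.

Tail partitions and the Δz analysis operate on the orientation-max,
*unsmoothed* per-probe values: smoothing exists to draw binding plots,
while tail membership and Δz are probe-level. Top and bottom sets each
hold round(0.05·n) members, ties broken by genome coordinate for
determinism. The Δz analysis regresses Δz = z₊UV − z₋UV on z₋UV (least
squares), reporting the slope, Pearson (headline) and Spearman
correlations, and the median Δz of both baseline tails. Under the affine
compression model z₊UV = (1−γ)z₋UV + c the slope is −γ: specificity loss
appears as a negative slope with the top tail falling and the bottom tail
rising.

Two estimation effects shape the slope's sampling behaviour and are worth
knowing when reading single runs: (i) replicate noise in the baseline z
enters Δz with coefficient −1, attenuating the expected slope by
−(1−γ)·σ²ₑ/(σ²_z + σ²ₑ) (about −0.03 at default settings); (ii) each
chamber's null σ rests on 116 controls, so the slope carries a per-run
scatter of roughly ±0.05. The recovery guarantee is therefore stated for
the mean over seeds (the acceptance test averages 20).

Motif comparison reports per-group median/IQR, median difference and the
two-sample Kolmogorov–Smirnov statistic. Region summaries (promoters,
external footprints) take user-supplied BED intervals — the package ships
no hard-coded promoter coordinates — and are circular-aware.

## Anisotropy and Hill fits

Anisotropy r = (I∥ − I⊥)/(I∥ + 2I⊥). Titrations are fit to

    r(x) = r_f + r_b · xⁿ / (K_Dⁿ + xⁿ)

with r_f the free-DNA baseline, r_b the bound amplitude, K_D in nM and n
the Hill coefficient. The published typesetting of this isotherm reads as
a product r_f·[r_b·xⁿ/(K_Dⁿ+xⁿ)], which is dimensionally degenerate (only
r_f·r_b is identifiable and the zero-concentration anisotropy would be 0);
the baseline-plus-amplitude form above matches the stated meanings of r_f
and r_b and is the default, with the literal product form available via
`form="product"`.

Fitting is bounded nonlinear least squares (r_f, r_b ∈ (0,1), K_D ∈
(10⁻³, 10³) nM, n ∈ (0.2, 10)) with a 9-point multi-start grid (K_D at the
half-rise concentration ×{0.3, 1, 3} crossed with n ∈ {1, 2, 4}), keeping
the lowest-RSS solution. The zero-concentration point participates and
anchors r_f. Parameter variances come from the covariance diagonal. A fit
is flagged unreliable when any start fails, a parameter lands on its
bounds, or var(K_D) > K_D² or var(n) > n² — the signature of an
unidentifiable design such as a titration with no upper plateau.

Replicates combine by the inverse-variance weighted mean
x̄ = Σ(xᵢ/σᵢ²)/Σ(1/σᵢ²) with weighted standard error
√{[Σ(xᵢ²/σᵢ²)/Σ(1/σᵢ²) − x̄²]·(m/(m−1))/m}; a single replicate has an
undefined SE, and a zero variance is an error (infinite weight).

## Damage model

Photolesions accrue linearly with UVC fluence: λ = rate·dose·length_kb,
default rate 0.01 lesions·kb⁻¹·(J/m²)⁻¹ (≈1 lesion per 10 kb at 10 J/m²,
the naked-DNA calibration; at 100 J/m² a 2.686-kb plasmid expects ≈3
lesions). Lesion-free molecules follow the Poisson zero class exp(−λ).
The long-amplicon qPCR inversion divides the long-product relative
amplification by the mitochondrial short-product amplification (copy
number), then maps it through −ln(·)·10/amplicon_kb to lesions per 10 kb.
The amplicon length is an explicit parameter defaulting to 10 kb (assay
variants use ~8.9–10 kb products). Negative estimates — amplification
above control — are preserved and flagged rather than clipped, keeping
below-detection time points representable. The mtDNA:nuclear copy ratio is
the ratio of the two short products.

## Synthetic-data generator

The generator's defaults are the study conditions: 16,569-nt circular
genome at GC 0.44, 33/2 tiling, 116 controls, 10 replicate spots, 30 nM
protein, 0 vs 1500 J/m² chambers, control level μ = 500 with occupancy
scale σ = 50 fluorescence units, 5% of windows planted at occupancy
z_high = 4 (dispersion 0.5; background N(0,1)), lognormal replicate noise
at CV 0.1, a ±50% multiplicative diagonal trend across the grid,
anisotropy noise SD 0.002 with triplicates over 12 concentrations spanning
0–15 nM, and qPCR CV 0.05 over the 0–50 J/m² dose series. Occupancy is
planted independently of motif content, so the motif comparison is null by
construction. All generators are bit-reproducible given (seed, config).

The UV effect is the minimal affine model reproducing the observed
signature: occupancy′ = (1−γ)·occupancy + γ·b with compression γ (default
0.5) and a uniform uplift b (default 0.5) applied to everything in the
irradiated chamber, controls included (their occupancy input is 0). No
mechanistic fidelity is claimed — no sequence-dependent lesion placement,
no cooperative lattice kinetics, no scanner-image artefacts. Consequently,
passing round-trip tests demonstrates that the pipeline recovers the
parameters of *this* model under realistic noise, not that real arrays are
free of effects outside it (saturation, probe-sequence synthesis bias,
orientation-specific double-stranding efficiency).

A consequence of controls having no sequence-level dispersion is that the
fitted null σ estimates the spread of control *medians* (≈1.25·CV·μ/√R ≈
19.8 at defaults), not the occupancy scale σ = 50; pipeline z-scores are
therefore occupancy × (σ/σ_medians). Slope-type statistics are invariant
to this common scale, and the null-recovery test checks the fitted σ
against an independent Monte-Carlo computation of the median spread.

## Problem sizes and tolerances

Tests and the acceptance script run at study scale where the claim demands
it (8,285 windows per orientation, ~167k spots per chamber — a chamber
pair takes well under a second through the full pipeline) and at reduced
scale (600-nt genome, 40 controls, 5 replicates) for unit-level contracts.
Key tolerances: Hill recovery at published parameters ±0.5 nM / ±0.5 in n
(observed recoveries are an order of magnitude tighter); slope recovery
±0.05 on the 20-seed mean; qPCR inversion exact to 1e-12; dose-response
rate within 10%; control z-scores |mean| < 0.2, SD within 1 ± 0.2, KS
statistic < 0.15 at n = 116.

## Known limitations

- The detrending smoother is a binned-median/Gaussian-kernel surface, not
  the exact local-regression variant any particular processing pipeline
  used; only its contract is guaranteed.
- The KDE-based null fit inflates σ by ~8% at n = 116 (see above); both
  chambers inflate equally, so comparative statistics are unaffected.
- Tail partitions are computed post-orientation-max (the alternative,
  per-orientation tails, is a documented switch point in the analysis, not
  currently exposed).
- The dipyrimidine counting convention is validated against magnitude and
  symmetry properties, not against the exact published per-sequence
  values, since the reference sequences are not bundled.
- `fit_titration_table` fits each replicate independently; no global
  multi-curve fitting, no instrument G-factor or total-intensity
  corrections.
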