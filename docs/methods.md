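# Methods

## The measurement model

One metaphase cell is imaged in a fluorescence channel; a chromosome ROI
is drawn on the morphology channel, independent of fluorescence. The
chain is:

1. **Background**: arithmetic mean and population SD of the pixels in the
   background mask (outside the cell). Population rather than sample SD
   because the mask is the whole pixel population of interest; at the
   ≥100 pixels required the distinction is numerically irrelevant, but the
   choice is recorded.
2. **Whole-cell segmentation**: pixels strictly above
   `bg_mean + 12·bg_sd`, keeping only the largest connected component
   (one cell per measurement; the threshold alone could admit debris). An
   empty result raises "no cell detected"; a second component ≥50% of the
   largest triggers an ambiguity warning.
3. **CER**: `(chrom_mean − bg_mean) / (cell_mean − bg_mean)`, unclamped.
   A chromosome mean below background yields a negative ratio with a
   warning rather than a silent zero, preserving estimator linearity for
   downstream statistics. A whole-cell mean at or below background is a
   degenerate-signal error.
4. **Expression QC**: pass iff the whole-cell mean lies in [50, 500],
   endpoints inclusive ("between 50 and 500" is ambiguous; inclusivity is
   the weaker reading and is recorded in the output metadata).
5. **Qualitative call**: cannot-call if the plate is not well-defined
   (an input flag — a human judgment the pipeline does not re-derive) or
   QC fails; otherwise positive iff CER > threshold. The threshold
   defaults to 1.6, the lower edge of the empirical 1.6–1.7 band, and the
   comparison is strict, so CER = 1.6 scores absent. Classifications at
   1.6 vs 1.7 differ exactly for CERs in (1.6, 1.7].

Box summaries use Tukey hinges (median-of-halves, median included in both
halves at odd n) with whiskers at the full range and the mean reported
separately; the quartile convention is logged because plotting software
conventions differ.

## The synthetic cell generator

The generator emulates the statistical structure the assay assumes, not
microscope optics:

* **Geometry** (defaults): 160×160 px frame; elliptical cell with
  semi-axes (48, 60) px; metaphase plate ellipse (26, 8) px at the
  equator; spindle region ellipse (22, 42) px minus the plate; two
  centrosome foci (Gaussian, σ = 3 px) at ±42 px along the long axis.
  No cell or camera dimensions are published for this assay, so all
  geometry values are package choices, fixed once.
* **Thickness**: projected dome `t = (1 − r²)^p` with `p = 0.5` (r =
  normalized elliptical radius). This one-parameter profile is the
  minimal way to reproduce the key geometric fact that a uniform
  fluorophore reads CER > 1 (≈1.44 under the defaults) because the plate
  occupies the thickest part of the cell; `p = 0` gives a flat slab and
  CER exactly 1 for a uniform reporter.
* **Compartments**: multiplicative enrichment over a cytoplasmic baseline
  of 1 on the plate, spindle region, and centrosome foci. The map is
  Gaussian-smoothed (σ = 2 px) before thickness modulation: compartment
  edges in real images are diffraction-soft, and soft edges make the
  hand-ROI emulation nearly unbiased. Smoothing a constant map is the
  identity, so the flat-uniform case stays exactly constant.
* **Expected image**: `offset + expression · t(x,y) · enrichment(x,y)`,
  with a 12-bit ceiling (4095) and offset 20. Expected intensities above
  the ceiling raise a saturation error by default; cohort generation
  instead clips and flags the cell (`saturated=True`), because strong
  overexpressors exist in real cohorts and must flow into the
  cannot-call path rather than crash a run.
* **Noise**: Poisson shot noise on the signal photons (default
  2 photons per intensity unit) plus Gaussian read noise (SD 0.5) added
  everywhere. The offset is electronic, not photonic, so the background
  carries read noise only — the physically standard CCD model. This
  matters: the segmentation threshold is 12 background SDs, and a noisy
  background would push it high enough to shave the dim rim off the cell
  and bias CER low for dim cells. Optional 2×2 block-mean binning
  (default off) mimics on-camera binning.
* **Expression**: per-cell lognormal, mean 220 CV 1.0 — strictly
  positive and right-skewed, producing the over/under-expression tails
  the cannot-call category exists for. The CER itself is expression-
  invariant by construction (the ratio cancels the level), which the
  tests verify.
* **Hand-ROI emulation**: the truth plate boundary displaced by a smooth
  mean-zero angular field (3 harmonics, clipped to ±2 px), i.e. locally
  varying dilation/erosion. A uniform whole-boundary dilation/erosion of
  the same magnitude was rejected: adding a full ring of dimmer
  cytoplasmic pixels is not offset by removing near-plate-intensity edge
  pixels, which biases measured CER low by ~0.1 at high enrichment,
  far beyond the tracing error it is meant to emulate.
* **Plate judgment**: each cell is flagged well-defined with probability
  0.85. Combined with the expression tails this puts the cannot-call
  proportion near 23% (computed from the lognormal window-exceedance
  probability), matching the 20–30% range typical of the assay.
* **Calibration**: the expected image is affine in the plate multiplier,
  so the multiplier that achieves any target noise-free CER is solved in
  closed form from two probe evaluations. The packaged catalogue
  (`data/constructs.yaml`) lists published per-construct mean CERs as
  targets; spindle/centrosome multipliers there are qualitative choices.

Under these defaults the measured-vs-truth bias of the full pipeline
(jittered ROI, 12-SD segmentation, default noise) is ≤ 0.03 at CER 2.45
with per-cell SD ≤ 0.03, so 10-cell cohorts recover calibration targets
within ±0.05.

What the generator does **not** emulate: DIC physics (the morphology
channel exists only as masks and a plate-defined flag), 3-D sectioning,
kinetochore-scale substructure, time-lapse dynamics, chromosome texture
within the plate, illumination flatness errors, and cell-to-cell shape
variation. Passing tests therefore demonstrate correctness of the
measurement and statistics under the assay's stated assumptions, not
robustness to every real-microscopy artifact.

## Statistics

* **Fisher's exact test** (2×2; positive vs pooled absent + cannot-call):
  two-sided p sums the hypergeometric probabilities, at fixed margins, of
  all tables no more probable than the observed one (relative tolerance
  1e−12 for float ties). Empty margins give p = 1 with a warning.
* **Exact Wilcoxon rank-sum**: mid-ranks; the null distribution of the
  rank sum over all C(n+m, n) group assignments is computed by a dynamic
  program over doubled ranks (exact integers even with ties), for any
  sample size — subset counts stay below 2^53, so float64 accumulation
  is exact. Two-sided p doubles the smaller tail, capped at 1. The
  doubled-tail convention's exact size at nominal 0.05 is 0.038–0.050
  for group sizes 6–10, i.e. valid and mildly conservative.
* **Anderson–Darling** (case both parameters estimated): A² from the
  sample mean and SD (ddof = 1), adjusted `A²* = A²(1 + 0.75/n +
  2.25/n²)`, rejection at A²* > 0.752 (α = 0.05, no level being stated
  for the original analysis); approximate p from the D'Agostino–Stephens
  piecewise exponential fit. Requires n ≥ 8; constant samples are an
  error.
* **Multiple testing**: pairwise comparisons against the reference
  construct are reported raw, as in the original analysis style; an
  optional Holm adjustment flag exists, default off. Stars map to
  p < 0.05 / 0.01 / 0.001.

## Fractionation

Generation and correction share one linear mixing model: with true
associated fraction `f` and carry-over `c`,
`CHR = total·(f + c(1−f))`, `CYTO = total·(1−f)(1−c)`. The proportional
correction `T = (f_obs − c)/(100 − c)·100` is that model's exact
inverse, hence the default; naive subtraction `f_obs − c` is reported
alongside because the published "approximately 30–40%" summary for a
~50% observed fraction with 17% carry-over is consistent with either and
the generative truth of real lysates is unknowable. Observations below
the contamination floor clip to 0 with a warning. Band quantification
itself (gel image → numbers) is out of scope; bands enter as numbers.

## Reproducibility and problem sizes

All randomness descends from explicit integer seeds via spawned
`SeedSequence` children; reruns of the pipeline reproduce every report
file byte for byte (CSV floats are formatted with `%.10g`; the run log
contains the seed and a hash of the scientific config). The test suite
and the acceptance script use cohorts of 10–30 cells, 100 seeded runs
for rank-ordering checks, and 200–500 replicates for null-calibration
checks — sizes chosen so the binomial/KS error bars are decisively
smaller than the effects being checked while a full run stays in the
minutes range on one CPU.

## Known limitations

* The 12-SD segmentation threshold makes the measured whole-cell mean
  slightly brighter than the true footprint mean for dim cells; under the
  default camera model the residual CER bias is within the documented
  ±0.05 envelope, but much noisier cameras would need the envelope
  re-derived.
* The qualitative plate-defined judgment is an input, not an inference;
  concordance results condition on it.
* The contamination correction assumes carry-over is proportional to the
  cytoplasmic pool and identical across proteins; a marker-specific
  pelleting affinity would violate it.
* User-supplied TIFFs are supported through the same quantification
  functions (image + ROI + background masks), but only single cells per
  frame; no interactive ROI drawing.
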