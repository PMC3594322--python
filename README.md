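# cermap

Quantification of reporter localization to mitotic chromosomes from
wide-field fluorescence images, with a fully ground-truthed synthetic
metaphase-cell generator, exact small-sample statistics, and
subcellular-fractionation densitometry.

## The problem

During mitosis, regulatory proteins such as cyclin B1–CDK1 partition
between the cytoplasm, the spindle, and the condensed chromosomes of the
metaphase plate. Wide-field imaging of GFP-fusion constructs can reveal
which sequence elements drive chromosome association, but eyeballing
"signal on the plate" is unreliable: the plate sits in the thickest part
of the cell, so even a freely diffusing fluorophore projects extra signal
there. A quantitative, background-aware ratio is needed, together with
statistics that remain valid at the 8–14 cells per construct that live
imaging typically yields.

## The measurement

For one metaphase cell, with `B` the mean background intensity outside the
cell, `C` the mean fluorescence over a chromosome ROI drawn on the
morphology (DIC) channel, and `W` the mean over the whole cell segmented
at threshold `B + 12·SD(background)` (largest connected component), the
**chromosome enrichment ratio** is

```
CER = (C − B) / (W − B)
```

CER > 1 means enrichment relative to the whole-cell average. Because of
the thickness geometry, an unenriched reporter reads ≈ 1.4 rather than
1.0; empirically a CER above ≈ 1.6 tracks qualitatively visible
chromosome association. Cells with whole-cell mean outside [50, 500]
(over/under-expression) or without a well-defined plate are scored
*cannot-call*; the rest are *positive* (CER > threshold) or *absent*.

Cohorts are compared with an exact Wilcoxon rank-sum test (full null
distribution via a shift-algorithm dynamic program, mid-ranks for ties),
qualitative call frequencies with Fisher's exact test (two-sided by
summed smaller probabilities), and each CER distribution is screened for
normality with the adjusted Anderson–Darling statistic
`A²* = A²(1 + 0.75/n + 2.25/n²)` against the 0.752 critical value.

The fractionation module turns blot densitometry (whole-cell extract,
chromosomal pellet, cytoplasmic supernatant) into chromosome-associated
percentages, `100·CHR/(CHR+CYTO)`, and corrects them for cytoplasmic
carry-over `c` measured with a pure-cytoplasm marker:
`T = (f_obs − c)/(100 − c)·100` (proportional mixing; naive subtraction
`f_obs − c` is reported alongside).

Because no public image data accompany this assay, the package includes a
synthetic metaphase-cell generator (elliptical cell, dome thickness
profile, plate/spindle/centrosome enrichment, lognormal per-cell
expression, Poisson + read noise, emulated hand-drawn ROIs) whose
noise-free CER is known analytically — enrichment multipliers are
calibrated in closed form so cohorts hit published mean-CER anchors such
as 1.87 (full-length construct) and 1.37 (free reporter).

## Worked example

```python
from cermap import CellGeometry, NoiseModel, generate_cell_image, profile_for_target_cer
from cermap.pipeline import quantify_synthetic_cell

geometry = CellGeometry()
for label, target in (("cyclin-B1-like", 1.87), ("free reporter", 1.37)):
    profile = profile_for_target_cer(label, target, geometry)
    cell = generate_cell_image(profile, geometry, NoiseModel(), seed=11)
    m = quantify_synthetic_cell(cell)
    print(f"{label}: CER {m.cer:.3f} (truth {cell.true_cer:.3f}), QC pass: {m.qc_pass}")
```

prints

```
cyclin-B1-like: CER 1.874 (truth 1.870), QC pass: True
free reporter: CER 1.372 (truth 1.370), QC pass: True
```

i.e. the measured ratio recovers the construct's ground-truth enrichment
to well under the 0.5 separation between the two constructs, despite
camera noise and the jittered hand ROI. The free reporter's 1.37 is the
cell-thickness effect, not chromosome binding. More narrative scripts —
cohort simulation with TIFF output, qualitative scoring, exact tests,
fractionation, and a five-construct experiment — live in `examples/`.

A thin CLI wraps the same functions: `cermap simulate`, `cermap
quantify`, `cermap score`, `cermap stats`, `cermap fractionate`, and
`cermap run <config.yaml>` for the full pipeline (see
`examples/experiment.yaml`).

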