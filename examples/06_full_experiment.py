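"""Run a full multi-construct experiment from a config and inspect the report.

Five constructs calibrated to published mean-CER anchors are simulated,
measured, scored, and compared against the free-reporter control with
exact tests; the report bundle (CSV tables, box plot, run log) lands in
example_output/experiment.
"""

from cermap import CellGeometry, ExperimentConfig, NoiseModel, load_catalog, run_experiment

geometry = CellGeometry()
catalog = load_catalog(geometry=geometry,
                       names=["WT_1_63", "WT_1_110", "WT_1_166", "WT_1_433", "GFP"])

config = ExperimentConfig(
    profiles=list(catalog.values()),
    n_cells=12,
    geometry=geometry,
    noise=NoiseModel(),
    reference_construct="GFP",
    seed=2024,
    output_dir="example_output/experiment",
)
report = run_experiment(config)

print(report.summary_table[["construct", "n_positive", "n_absent", "n_cannot_call",
                            "cer_mean", "cer_median"]].to_string(index=False))
print()
print(report.comparisons[["construct", "wilcoxon_p", "wilcoxon_stars",
                          "fisher_p", "fisher_stars"]].to_string(index=False))
# Cohort mean CERs recover the calibration anchors (2.45 > 2.34 > 2.14 >
# 1.87 > 1.37) and every enriched construct separates from the reporter
# control; rerunning with the same seed reproduces the files byte for byte.
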