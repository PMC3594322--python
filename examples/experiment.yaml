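# Five-construct experiment against the free-reporter control.
# Run with:  cermap run examples/experiment.yaml -o example_output/run
constructs: [WT_1_63, WT_1_110, WT_1_166, WT_1_433, GFP]
n_cells: 12
reference_construct: GFP
cer_threshold: 1.6
seed: 2024
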