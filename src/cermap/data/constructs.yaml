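# Named reporter-construct localization profiles.
#
# target_cer values are the published per-construct mean chromosome
# enrichment ratios used as calibration anchors: the generator solves for
# the chromosome-enrichment multiplier that reproduces each target on the
# noise-free expected image under the chosen geometry.  Spindle and
# centrosome multipliers are qualitative package choices (full-length
# cyclin B1 decorates spindle and centrosomes; free GFP shows mild
# spindle-proximal signal; short fragments largely do not), as the source
# data report no numbers for them.
constructs:
  WT_1_433:   {target_cer: 1.87, spindle_enrich: 1.3, centrosome_enrich: 3.0}
  GFP:        {target_cer: 1.37, spindle_enrich: 1.15, centrosome_enrich: 1.0}
  WT_1_15:    {target_cer: 1.39, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  WT_1_20:    {target_cer: 1.55, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  WT_1_41:    {target_cer: 1.97, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  WT_1_63:    {target_cer: 2.45, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  WT_1_110:   {target_cer: 2.34, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  WT_1_166:   {target_cer: 2.14, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  WT_21_433:  {target_cer: 1.35, spindle_enrich: 1.3, centrosome_enrich: 3.0}
  WT_42_433:  {target_cer: 1.20, spindle_enrich: 1.3, centrosome_enrich: 3.0}
  WT_21_166:  {target_cer: 1.66, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  WT_42_166:  {target_cer: 1.37, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  WT_21_110:  {target_cer: 1.81, spindle_enrich: 1.2, centrosome_enrich: 1.0}
  WT_42_110:  {target_cer: 1.39, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  D3-8_1_433: {target_cer: 1.50, spindle_enrich: 1.3, centrosome_enrich: 3.0}
  R42A_1_63:  {target_cer: 2.09, spindle_enrich: 1.2, centrosome_enrich: 1.0}
  R42A_1_110: {target_cer: 2.18, spindle_enrich: 1.2, centrosome_enrich: 1.0}
  D3-8_R42A_1_63:  {target_cer: 1.39, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  D3-8_R42A_1_110: {target_cer: 1.48, spindle_enrich: 1.1, centrosome_enrich: 1.0}
  R42A_21_110:     {target_cer: 1.50, spindle_enrich: 1.1, centrosome_enrich: 1.0}
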