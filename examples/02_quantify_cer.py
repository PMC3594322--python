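"""Measure the chromosome enrichment ratio of single synthetic cells.

Generates one enriched and one reporter-only cell and runs the full
measurement chain: background estimation outside the cell, whole-cell
segmentation at 12 background SDs, mean intensities, and the
background-subtracted ratio.
"""

from cermap import CellGeometry, NoiseModel, generate_cell_image, profile_for_target_cer
from cermap.pipeline import quantify_synthetic_cell

geometry = CellGeometry()
noise = NoiseModel()

for label, target in (("cyclin-B1-like", 1.87), ("free reporter", 1.37)):
    profile = profile_for_target_cer(label, target, geometry)
    cell = generate_cell_image(profile, geometry, noise, seed=11)
    m = quantify_synthetic_cell(cell)  # uses the emulated hand-drawn ROI
    print(
        f"{label}: background {m.background.mean:6.2f} ± {m.background.sd:.2f}, "
        f"cell mean {m.cell_mean:6.1f}, plate mean {m.chrom_mean:6.1f}, "
        f"CER {m.cer:.3f} (truth {cell.true_cer:.3f}), QC pass: {m.qc_pass}"
    )

# The measured CER tracks the analytic truth to a few percent despite shot
# noise, read noise, and the jittered hand ROI.  A CER near 1.4 for the
# free reporter is expected: the metaphase plate sits in the thickest part
# of the cell, so even an unenriched fluorophore projects more signal
# there than the whole-cell average.
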