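"""Simulate one cell, segment it, and measure its membrane-to-cytoplasm ratio.

The generator renders a cell with a bright 5-px membrane rim (300 a.u.)
over a dimmer cytoplasm (100 a.u.) plus Poisson noise, so the true M-C
ratio is 3.0. The pipeline detects the cell on a blurred copy, anchors a
5-px band on the membrane, and measures on the raw image.
"""

from memratio import (ImageMeta, SegmentationParams, SyntheticCellSpec,
                      classify_localization, generate_cell_image, measure_cell,
                      segment_image)

meta = ImageMeta(width=160, height=160)
spec = SyntheticCellSpec(center=(80, 80), semi_axes=(36, 28))  # true ratio 3.0
image, truth = generate_cell_image(spec, meta, seed=42)

params = SegmentationParams(min_cell_area=200)
(cell, rois), = segment_image(image, params)
m = measure_cell(image, rois)
call = classify_localization(m)

print(f"true M-C ratio:      {truth.true_mc_ratio:.3f}")
print(f"recovered M-C ratio: {m.mc_ratio:.3f}")
print(f"mean membrane / cytoplasm intensity: {m.mean_membrane:.1f} / {m.mean_cytoplasm:.1f} a.u.")
print(f"expression level (summed integrated intensity): {m.expression_level:.0f} a.u.")
print(f"localization call at threshold 1.2: {call}")
# The recovered ratio sits within a few percent of truth; the residual bias
# comes from band pixels straddling the rim edge.
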