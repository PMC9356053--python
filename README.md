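# memratio

Quantification of plasma-membrane recruitment in confocal fluorescence
images of adherent cells. The package measures, for each cell, the
**membrane-to-cytoplasm ratio**

&nbsp;&nbsp;&nbsp;&nbsp;M-C ratio = ⟨I⟩<sub>membrane</sub> / ⟨I⟩<sub>cytoplasm</sub>,

the mean raw fluorescence over a thin band just inside the cell edge
divided by the mean over the deeper cytoplasm — the standard readout for
how strongly a tagged protein (a lipid-anchored GTPase, a curvature
sensor, a lipid probe) associates with the plasma membrane. Around this
core it provides:

- **Automated ROI extraction** — the manual "5-pixel line ROI traced just
  inside the membrane" becomes a deterministic depth band: cells are
  detected on a Gaussian-blurred copy (Otsu or fixed threshold), and the
  membrane band is anchored on the brightest depth range of the footprint;
  all statistics are then computed on the raw image.
- **Localization calling** — cells are classified PM vs Cyt by an M-C
  ratio threshold (default 1.2), and populations summarized as PM/Cyt
  fractions.
- **Hyposmotic-shock traces** — per-cell integrated membrane intensity
  over a time-lapse (frames every 30 s, shock after 1 min, medium diluted
  1:6 from 300 to 50 mM), normalized to the first three points, with the
  percentage change ΔI = ((I1 − I0)/I0)·100 under two window conventions.
- **Statistics** — two-tailed Welch *t*-tests with Satterthwaite degrees
  of freedom (stars \* p 0.01–0.05, \*\* 0.001–0.01, \*\*\* <0.001;
  error bars ±0.5 SD), membrane-pixel Pearson colocalization with
  Fisher-z 95% CI and the r > 0.4 moderate-to-strong rule, and binned
  co-expression analysis (expression bins 0–8000, 8000–25 000,
  25 000–40 000, 40 000–65 000 a.u.; bin means ± SEM; linear correlation
  with standard error and CI).
- **A seeded synthetic-image generator** with exported ground truth
  (masks, true ratios, true traces, true channel correlation), so every
  stage is validated against known answers without raw microscopy data.

## Worked example

```python
from memratio import (ImageMeta, SegmentationParams, SyntheticCellSpec,
                      classify_localization, generate_cell_image,
                      measure_cell, segment_image)

meta = ImageMeta(width=160, height=160)
spec = SyntheticCellSpec(center=(80, 80), semi_axes=(36, 28))  # true ratio 3.0
image, truth = generate_cell_image(spec, meta, seed=42)
(cell, rois), = segment_image(image, SegmentationParams(min_cell_area=200))
m = measure_cell(image, rois)
print(m.mc_ratio, classify_localization(m))
```

prints

```
true M-C ratio:      3.000
recovered M-C ratio: 2.806
mean membrane / cytoplasm intensity: 280.0 / 99.8 a.u.
localization call at threshold 1.2: PM
```

(from `examples/01_measure_mc_ratio.py`): the pipeline recovers the true
ratio to within a few percent — the small negative bias comes from band
pixels straddling the rim edge — and correctly calls the cell
membrane-localized. The other scripts in `examples/` walk through the
shock-trace analysis, membrane colocalization, binned co-expression and
the end-to-end two-condition comparison; each prints the numbers it
computes and what they mean.

A `memratio` command-line tool wraps the same library for batch use:
`memratio simulate ...`, `memratio segment`, `memratio quantify`,
`memratio shock`, `memratio coloc`, `memratio coexpress`,
`memratio compare`, and `memratio run` for the end-to-end synthetic demo.
Every run writes its resolved configuration and a config hash next to
its outputs.

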