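# Methods

## The measurement model

A cell expressing a fluorescently tagged membrane-binding protein is
imaged as a 2-D confocal section: a bright rim where the plasma membrane
crosses the focal plane, a dimmer cytoplasm fill, and dark background.
The quantity of interest is the membrane-to-cytoplasm ratio

    M-C ratio = mean(I_raw over membrane band) / mean(I_raw over cytoplasm),

which is invariant to multiplicative gain (laser power, detector gain,
expression level) but not to additive offset: adding a constant
background pulls the ratio toward 1. No background subtraction is
applied — the workflow this package reproduces performs none — and the
optional background-ring estimator (`estimate_background_ring`) exists
only so users can check offset sensitivity. Per-cell expression level is
the summed integrated intensity (mean × pixel count) of the membrane and
cytoplasm regions.

## ROI construction

Manual practice traces a 5-pixel-wide line on top of the membrane, as
close to the cell interior as possible, so that signal from touching
neighbors is excluded. The automated analogue:

1. **Detection blur.** The image is convolved with a Gaussian of full
   width `blur_size` = 5 px (σ = 5/3 px — "size" interpreted as kernel
   width, the common GUI convention; configurable). The blurred copy is
   used *only* for detection; measurement always reads the raw image.
2. **Footprint.** Pixels above the threshold (Otsu by default; a fixed
   value for noiseless work) are filled, labeled, and filtered by
   `min_cell_area`; objects touching the image border are discarded.
   Touching cells merge into one connected component — no splitting is
   attempted; instance masks can be supplied externally (e.g. from the
   generator's ground truth), and because each band is carved from its
   own footprint it can never contain a neighbor's pixels.
3. **Depth bands.** With `depth` the Euclidean distance from the
   footprint edge, the membrane band is `offset < depth ≤ offset + 5`
   and the cytoplasm is `depth > offset + 5 + guard_gap`
   (`guard_gap` = 2 px keeps rim bleed-through out of the cytoplasm
   estimate; the ring between band and cytoplasm belongs to neither).
4. **Intensity anchoring.** A thresholded boundary sits 1–2 px outside
   the true membrane (the blur halo clears the threshold), which would
   dilute the band mean by ~25%. The anchor `offset` is therefore chosen
   in 0..`max_edge_offset` (default 3) to maximize the band's mean raw
   intensity — the deterministic equivalent of drawing the line on top
   of the membrane. With `max_edge_offset = 0`, or when no intensity
   image is passed, the construction reduces to the plain erosion band.

Coordinates are pixel-centered, row-major, origin top-left; masks export
as label TIFFs and boundaries as ImageJ polygon `.roi` files (written by
a small built-in encoder of the documented binary format).

No focus/health criterion is implemented: the only inclusion rules are
area and border contact, and the package does not claim to reproduce a
by-eye cell selection.

## Localization calling

The qualitative PM-vs-cytoplasm call ("signal at least partially on the
membrane") is replaced by a threshold on the M-C ratio, default 1.2.
The value is a package decision, not a measured constant: it encodes
"detectable rim contrast" and achieves ≥95% agreement with generator
ground-truth labels for populations with ratios 0.9 (Cyt) vs 2.5 (PM)
under Poisson noise. Every summary records the threshold used.

## Hyposmotic shock

Protocol defaults: 30-s frame cadence; shock after 60 s (three pre-shock
frames at t = 0, 30, 60 s); 300 s of post-shock imaging; medium diluted
1:6 from 300 mM to 50 mM (a control run is `dilution_ratio = 1`). The
per-cell readout is the integrated raw intensity over a membrane ROI
frozen on a pre-shock frame — swelling that moves the membrane off the
ROI registers as intensity loss, which is the intended signal, so no
tracking is attempted.

ΔI = ((I1 − I0)/I0)·100 with I0 the mean of points 1–3. Two published
window conventions for I1 coexist and disagree on still-decaying traces:
**methods** (mean from point 4 to the end; the default, from the formula
paragraph) and **caption** (mean of the last four points). Both are
implemented behind `window_convention`; every result records which was
used, and the package takes no position on which produced any published
figure. ΔI is exactly invariant to the first-three-points normalization,
and for a monotonically decreasing trace caption-ΔI ≤ methods-ΔI.

## Statistics

- **Welch t-test** (scipy `ttest_ind(equal_var=False)`, which returns the
  Satterthwaite df). Degenerate zero-variance groups: equal means give
  t = 0, p = 1; unequal means give p = 0. The Satterthwaite df always
  lies in [min(n₁,n₂) − 1, n₁ + n₂ − 2].
- **Stars**: the printed ranges (* 0.01–0.05, ** 0.001–0.009,
  *** <0.001) leave 0.009–0.01 unmapped; the implementation closes them
  into contiguous half-open intervals (*** p<0.001, ** [0.001, 0.01),
  * [0.01, 0.05), ns ≥ 0.05) so the map is total on [0, 1].
- **Error bars**: ±0.5 sample SD (n−1 denominator), the plotting
  convention of the workflow.
- **Correlation**: Pearson r with the analytic standard error
  (1 − r²)/√(n − 1), a Fisher-z 95% CI (the CI method is a package
  choice; none was prescribed), significance from the exact correlation
  test at α = 0.05, and CI-excludes-zero readable from the interval —
  both significance routes are reported since the "linear correlation
  test" machinery was unspecified. r > 0.4 labels membrane
  colocalization moderate-to-strong.
- **Binning**: expression bins [0, 8000), [8000, 25 000),
  [25 000, 40 000), [40 000, 65 000]; half-open with the last edge
  closed; out-of-range cells are excluded and counted. SEM = SD/√n.
- No multiple-testing correction: comparisons are reported
  per-comparison in one table so users can correct downstream.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not the optics. A cell is an ellipse whose boundary radius is modulated
by a 3-lobe sinusoid (`boundary_irregularity`, default 0.05); the
membrane rim is the depth band of `membrane_rim_width` = 5 px; rendering
assigns constant region intensities (defaults 300/100/5 a.u. for
rim/cytoplasm/background, chosen to give clear contrast within 16-bit
range and, with the default geometry, expression levels spanning the
four analysis bins — no published intensity scale constrains them), then
applies Poisson noise (confocal photon statistics) with optional
Gaussian read noise. Puncta are Gaussian spots on the rim. Default frame
size is 512×512 for speed (tests use 160×160); the metadata carries the
acquisition-scale 2048×2048 / 120 nm / 16-bit values as a one-line
configuration change.

Dual-channel images draw rim-pixel fluctuations (CV 0.25) from a
bivariate Gaussian with the target correlation ρ, so the sample r
converges to ρ and ρ = ±1 gives exactly affine channels. Population
ratios are fixed or lognormal (right-skewed, as transfection levels
are). Shock movies follow a trace model: **plateau** — a linear ramp
down by `drop_fraction` over `time_constant` seconds, then constant
(chosen over an exponential approach so the plateau level is reached
exactly, making noiseless round-trip tests exact); **gradual** — a
constant-slope decline that never levels off. The noiseless integrated
rim trace is returned as ground truth.

What the generator does **not** emulate — PSF blur, z-sectioning,
intensity gradients within regions, nuclei and organelles, cell
motility, real segmentation ambiguity at low contrast — bounds what
passing tests show: they validate the measurement and statistics
machinery against known truth, not segmentation robustness on real
micrographs.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is bit-reproducible, and the end-to-end runner spawns
  per-condition seeds from one master seed via `SeedSequence`, writing
  byte-identical tables for identical configs.
- Noiseless rendering is exact: region means equal specified intensities
  to machine precision, which several tests rely on.
- Saturated cells (pixels at the bit-depth maximum) are flagged, not
  dropped; no saturation rule was prescribed.
- Problem sizes in tests and in `scripts/acceptance.py` (160–192 px
  frames, 100–200 cells, 10 000 null replicates) were chosen as the
  smallest sizes at which the sampling-theory checks (Poisson SE,
  Fisher-z intervals, binomial CIs) are well inside their asymptotic
  regimes.
- Known limitations: no splitting of touching cells at detection; the
  intensity-anchored band assumes the rim is the brightest depth range
  (true for membrane-localized constructs; for purely cytoplasmic cells
  the anchor drifts inward, which only reinforces a correct "Cyt" call);
  the PM/Cyt threshold is a convention, not an estimate of the visual
  criterion.
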