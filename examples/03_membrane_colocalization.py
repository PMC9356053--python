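"""Pixelwise colocalization of two channels on the plasma membrane.

Two channels are generated with membrane-pixel fluctuations correlated at
rho = 0.7 — emulating a membrane-recruited GTPase co-expressed with a
curvature sensor. Pearson's r over the membrane mask, the regression
slope, and the Fisher-z 95% CI are reported; r > 0.4 is the threshold
for moderate-to-strong colocalization.
"""

from memratio import (ImageMeta, SyntheticCellSpec, generate_dual_channel,
                      membrane_pearson)

meta = ImageMeta(width=192, height=192)
spec = SyntheticCellSpec(center=(96, 96), semi_axes=(44, 36), noise_model="none")
(ch1, ch2), truth = generate_dual_channel(spec, rho=0.7, meta=meta, seed=5)

res = membrane_pearson(ch1, ch2, truth.membrane_mask)
print(f"membrane pixels analyzed: {res.n}")
print(f"Pearson r = {res.r:.3f} (target rho = {truth.channel_rho})")
print(f"slope = {res.slope:.3f}, stderr_r = {res.stderr_r:.4f}")
print(f"95% CI for r: [{res.ci95[0]:.3f}, {res.ci95[1]:.3f}]")
print(f"colocalization strength: {res.strength_label}")
# The recovered r falls inside the Fisher-z interval around 0.7 and clears
# the 0.4 threshold, so the two signals are called colocalized on the PM.
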