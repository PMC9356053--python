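"""End-to-end demo: two conditions with shifted true M-C ratios, compared
with a Welch t-test.

Simulates 50 cells per condition (true ratios 1.6 vs 2.4, emulating an
untreated vs growth-factor-treated population), runs the full
segment-and-measure pipeline, and writes the per-cell, comparison and
localization tables that a real-data run would produce.
"""

import tempfile
from pathlib import Path

import pandas as pd

from memratio import ConditionConfig, RunConfig, run_endtoend

config = RunConfig(
    conditions=[ConditionConfig("TGFb-", n_cells=50, true_mc_ratio=1.6),
                ConditionConfig("TGFb+", n_cells=50, true_mc_ratio=2.4)],
    image_size=160, seed=1, min_cell_area=200,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = run_endtoend(config, Path(tmp) / "run")
    comp = pd.read_csv(paths["comparisons"]).iloc[0]
    loc = pd.read_csv(paths["localization"])

print(f"{comp.group_a}: mean M-C ratio {comp.mean_a:.3f} +/- {comp.half_sd_a:.3f} (0.5 SD)")
print(f"{comp.group_b}: mean M-C ratio {comp.mean_b:.3f} +/- {comp.half_sd_b:.3f} (0.5 SD)")
print(f"Welch t = {comp.t:.2f}, df = {comp.df:.1f}, p = {comp.p_value:.2e} {comp.stars}")
print(loc[["condition", "fraction_pm", "fraction_cyt"]].to_string(index=False))
# The treated condition's higher measured ratio and PM fraction recover the
# effect built into the generator; stars follow the p-value ranges
# (* 0.01-0.05, ** 0.001-0.01, *** <0.001).
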