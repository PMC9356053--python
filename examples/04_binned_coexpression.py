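"""Binned co-expression analysis: does expressing a suppressor relocate a
membrane protein to the cytoplasm?

A 200-cell population is simulated in which the M-C ratio declines
linearly with the co-expressed construct's expression level
(slope -2e-5 per a.u.). Cells are grouped into four expression bins
(0-8000, 8000-25000, 25000-40000, 40000-65000 a.u.); bin means with SEM
plus the linear correlation test quantify the trend.
"""

from memratio import (bin_coexpression, correlation_with_ci,
                      generate_coexpression_population)

table = generate_coexpression_population(200, mc_slope=-2e-5, noise_sd=0.1, seed=3)
binned = bin_coexpression(table)

print("bin (a.u.)            n    mean expr    mean M-C   SEM")
for b in range(len(binned.n)):
    lo, hi = binned.bin_edges[b], binned.bin_edges[b + 1]
    print(f"{lo:>6.0f}-{hi:<8.0f} {binned.n[b]:>6d} {binned.mean_x[b]:>11.0f} "
          f"{binned.mean_mc_ratio[b]:>10.3f} {binned.sem[b]:>7.3f}")

res = correlation_with_ci(table["expression_level"], table["mc_ratio"])
print(f"\nlinear correlation: r = {res.r:.3f} +/- {res.stderr_r:.3f}, "
      f"95% CI [{res.ci95[0]:.3f}, {res.ci95[1]:.3f}], p = {res.p_value:.2e}")
# Strictly decreasing bin means and a significantly negative r show the
# dose-dependent loss of membrane localization built into the population.
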