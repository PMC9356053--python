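"""Group comparisons, colocalization correlation, and binned co-expression.

Conventions mirrored from the quantification workflow this package
implements: two-tailed Welch t-test with Satterthwaite degrees of freedom
for M-C ratio group comparisons; significance stars *** p < 0.001,
** p in [0.001, 0.01), * p in [0.01, 0.05), ns otherwise; plotting error
bars of +/- 0.5 sample SD; pixelwise Pearson correlation over the
membrane mask with a Fisher-z 95% CI and an r > 0.4 threshold for
"moderate-to-strong" colocalization; co-expression data binned into
four half-open expression bins [0, 8000), [8000, 25000), [25000, 40000),
[40000, 65000] with per-bin means and SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Image2D
from .quantify import CellMeasurement

__all__ = [
    "TestResult",
    "CorrelationResult",
    "BinnedSeries",
    "DEFAULT_BIN_EDGES",
    "STRONG_CORRELATION_THRESHOLD",
    "welch_ttest",
    "assign_stars",
    "group_error_bars",
    "membrane_pearson",
    "bin_coexpression",
    "correlation_with_ci",
]

#: expression-level bin edges (a.u.); bins are [lo, hi), last bin closed.
DEFAULT_BIN_EDGES = (0.0, 8000.0, 25000.0, 40000.0, 65000.0)

#: Pearson r above which membrane colocalization is called moderate-to-strong.
STRONG_CORRELATION_THRESHOLD = 0.4


@dataclass
class TestResult:
    t_statistic: float
    df: float  # Welch-Satterthwaite, non-integer allowed
    p_value: float
    stars: str
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    group_ns: tuple[int, int]
    alpha: float = 0.05


@dataclass
class CorrelationResult:
    r: float
    slope: float
    stderr_r: float
    ci95: tuple[float, float]  # Fisher-z interval for r
    n: int
    p_value: float
    significant: bool  # p < alpha
    strength_label: str  # "weak" or "moderate-to-strong"
    alpha: float = 0.05


@dataclass
class BinnedSeries:
    bin_edges: tuple[float, ...]
    mean_x: np.ndarray  # per-bin mean expression, a.u.
    mean_mc_ratio: np.ndarray
    sem: np.ndarray  # per-bin SEM of the M-C ratio
    n: np.ndarray  # per-bin cell count
    n_excluded: int  # cells outside the binned range


def assign_stars(p: float) -> str:
    """Map a p-value to the significance-star scheme.

    Contiguous half-open intervals: *** p < 0.001, ** [0.001, 0.01),
    * [0.01, 0.05), ns >= 0.05 — a total function on [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def welch_ttest(group_a, group_b, alpha: float = 0.05) -> TestResult:
    """Two-tailed Welch t-test with Satterthwaite degrees of freedom.

    Handles the degenerate case of zero variance in both groups: equal
    means give t = 0, p = 1 by convention; unequal means with no
    within-group scatter give p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain finite values only")
    sds = (float(a.std(ddof=1)), float(b.std(ddof=1)))
    means = (float(a.mean()), float(b.mean()))
    ns = (len(a), len(b))
    if sds[0] == 0.0 and sds[1] == 0.0:
        df = float(min(ns) - 1)
        if means[0] == means[1]:
            t, p = 0.0, 1.0
        else:
            t = float("inf") if means[0] > means[1] else float("-inf")
            p = 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return TestResult(t_statistic=t, df=df, p_value=p, stars=assign_stars(p),
                      group_means=means, group_sds=sds, group_ns=ns, alpha=alpha)


def group_error_bars(values) -> float:
    """Half the sample SD — the +/- 0.5 SD error-bar plotting convention."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    return 0.5 * float(v.std(ddof=1))


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n < 4:
        raise ValueError("Fisher-z interval needs n >= 4")
    r = min(max(r, -0.9999999), 0.9999999)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def _pearson_with_ci(x: np.ndarray, y: np.ndarray, alpha: float) -> CorrelationResult:
    n = len(x)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    r, p = float(r), float(p)
    slope = float(np.polyfit(x, y, 1)[0])
    stderr_r = (1.0 - r**2) / np.sqrt(n - 1)
    lo, hi = _fisher_ci(r, n, alpha)
    return CorrelationResult(
        r=r, slope=slope, stderr_r=float(stderr_r), ci95=(lo, hi), n=n,
        p_value=p, significant=p < alpha,
        strength_label=("moderate-to-strong" if r > STRONG_CORRELATION_THRESHOLD
                        else "weak"),
        alpha=alpha,
    )


def membrane_pearson(channel_1: Image2D, channel_2: Image2D,
                     membrane_mask: np.ndarray, alpha: float = 0.05,
                     ) -> CorrelationResult:
    """Pixelwise Pearson correlation of two channels over the membrane mask.

    The same mask is applied to both channels (sequentially imaged
    channels share geometry). Returns r, least-squares slope of channel 2
    on channel 1, the analytic standard error (1 - r^2)/sqrt(n - 1), and
    a Fisher-z 95% CI; colocalization is labeled moderate-to-strong when
    r exceeds 0.4.
    """
    if channel_1.shape != channel_2.shape or membrane_mask.shape != channel_1.shape:
        raise ValueError("channels and mask must share one shape")
    n = int(membrane_mask.sum())
    if n < 10:
        raise ValueError(f"membrane mask has only {n} pixels (need >= 10)")
    x = channel_1.pixels[membrane_mask]
    y = channel_2.pixels[membrane_mask]
    return _pearson_with_ci(x, y, alpha)


def bin_coexpression(measurements, edges=DEFAULT_BIN_EDGES) -> BinnedSeries:
    """Bin cells by expression level and average the M-C ratio per bin.

    Bins are half-open [lo, hi) with the last bin closed at its upper
    edge; cells outside the total range are excluded and counted.
    Accepts a list of CellMeasurement or a DataFrame with
    ``expression_level`` and ``mc_ratio`` columns.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if isinstance(measurements, pd.DataFrame):
        expr = measurements["expression_level"].to_numpy(dtype=float)
        ratio = measurements["mc_ratio"].to_numpy(dtype=float)
    else:
        expr = np.array([m.expression_level for m in measurements], dtype=float)
        ratio = np.array([m.mc_ratio for m in measurements], dtype=float)
    in_range = (expr >= edges[0]) & (expr <= edges[-1])
    if not in_range.any():
        raise ValueError("no measurement falls inside the binned range")
    idx = np.digitize(expr, edges, right=False) - 1  # [lo, hi) bins
    idx[expr == edges[-1]] = len(edges) - 2  # close the last bin
    n_bins = len(edges) - 1
    mean_x = np.full(n_bins, np.nan)
    mean_r = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = in_range & (idx == b)
        counts[b] = sel.sum()
        if counts[b] >= 1:
            mean_x[b] = expr[sel].mean()
            mean_r[b] = ratio[sel].mean()
            sem[b] = (ratio[sel].std(ddof=1) / np.sqrt(counts[b])
                      if counts[b] > 1 else 0.0)
    return BinnedSeries(bin_edges=edges, mean_x=mean_x, mean_mc_ratio=mean_r,
                        sem=sem, n=counts, n_excluded=int((~in_range).sum()))


def correlation_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Linear correlation of M-C ratio against expression level.

    Returns the Pearson coefficient with its standard error, the
    least-squares slope, a Fisher-z 95% CI, and significance from the
    exact correlation test at the chosen alpha. Significance by CI
    exclusion of zero can be read directly off ``ci95``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    return _pearson_with_ci(x, y, alpha)
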