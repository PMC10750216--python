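"""Rank-based comparison of per-ROI statistics across disease groups.

The Kruskal–Wallis H test is assembled here from first principles (mid-ranks,
tie correction, chi-square approximation) rather than delegated, because it
is the defined comparison of this analysis:

    H = [ 12 / (N(N+1)) · Σ_j R_j²/n_j − 3(N+1) ] / [ 1 − Σ_t (t³−t)/(N³−N) ]

with R_j the rank sum of group j over the pooled mid-ranks, N the pooled
size, and the sum over tie groups of size t.  The p-value uses the χ²_{k−1}
survival function, adequate for the group sizes arising here (tens of ROIs
per group); a flag is raised when any group has fewer than 5 values, where
the approximation degrades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, rankdata

ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float  # tie-corrected H
    df: int
    pvalue: float
    significant: bool  # at α = 0.05
    degenerate: bool = False  # all pooled values identical
    small_groups: bool = False  # some n_j < 5: χ² approximation is rough


@dataclass
class BoxplotStats:
    """Five-number boxplot summary with 1.5·IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis rank-sum test across ≥ 2 groups of values.

    ``groups`` is a sequence of 1D value arrays (or a dict mapping group
    label to values).  All pooled values identical is degenerate: H = 0,
    p = 1, flagged.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    sizes = np.array([len(a) for a in arrays])
    n_total = int(sizes.sum())
    if n_total < k + 1:
        raise ValueError("need at least one more value than groups")

    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, k - 1, 1.0, False, degenerate=True,
                          small_groups=bool((sizes < 5).any()))

    ranks = rankdata(pooled)  # mid-ranks for ties
    h = 0.0
    start = 0
    for n_j in sizes:
        r_j = ranks[start : start + n_j].sum()
        h += r_j**2 / n_j
        start += n_j
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)

    _, counts = np.unique(pooled, return_counts=True)
    ties = counts[counts > 1]
    correction = 1.0 - (ties**3 - ties).sum() / (n_total**3 - n_total)
    h /= correction

    p = float(chi2.sf(h, k - 1))
    return TestResult(
        statistic=float(h),
        df=k - 1,
        pvalue=p,
        significant=p < ALPHA,
        small_groups=bool((sizes < 5).any()),
    )


def summarize_boxplot(values) -> BoxplotStats:
    """Boxplot summary with quartiles by the median-of-halves convention.

    The sorted data are split at the median (which is excluded from both
    halves when n is odd); Q1 and Q3 are the medians of the halves.
    Whiskers reach the most extreme data points within 1.5·IQR of the
    quartiles; points beyond are outliers.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(v)
    if n == 0:
        raise ValueError("empty group")
    median = float(np.median(v))
    if n == 1:
        return BoxplotStats(median, median, median, median, median)
    half = n // 2
    lower, upper = v[:half], v[n - half:]
    q1, q3 = float(np.median(lower)), float(np.median(upper))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotStats(
        median, q1, q3, float(inside.min()), float(inside.max()), outliers
    )
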