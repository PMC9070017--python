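"""Nonparametric statistical battery used throughout the analyses.

Thin, contract-stable wrappers over scipy.stats: two-tailed Wilcoxon
signed-rank for paired medians, Mann-Whitney U for independent groups
(midranks, tie-corrected variance), Spearman rank correlation, and
Shapiro-Wilk normality. Degenerate inputs (all-zero differences,
constant vectors) are flagged rather than raising, since they occur
legitimately on synthetic edge cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_two_sided: float
    n: int
    degenerate: bool = False


def paired_median_test(x, y) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the p-value is exact for up to 25
    nonzero differences (no ties) and a continuity-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult("wilcoxon_signed_rank", np.nan, np.nan, 0,
                          degenerate=True)
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = sstats.wilcoxon(x, y, zero_method="wilcox", correction=True,
                          alternative="two-sided", method=method)
    return TestResult("wilcoxon_signed_rank", float(res.statistic),
                      float(res.pvalue), int(nz.size))


def independent_test(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult("mann_whitney_u", float(res.statistic),
                      float(res.pvalue), int(a.size + b.size))


def rank_correlation(x, y) -> TestResult:
    """Spearman rank-order correlation with a two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult("spearman", np.nan, np.nan, int(x.size),
                          degenerate=True)
    rho, p = sstats.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), int(x.size))


def normality_check(x) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.unique(x).size == 1:
        return TestResult("shapiro_wilk", np.nan, np.nan, int(x.size),
                          degenerate=True)
    w, p = sstats.shapiro(x)
    return TestResult("shapiro_wilk", float(w), float(p), int(x.size))
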