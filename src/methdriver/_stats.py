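"""Shared statistical primitives: rank tests and FDR adjustment.

The exact/asymptotic Mann-Whitney switch lives here so the expression,
methylation and BSP modules all test group differences identically.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# combined sample size at or below which the exact null distribution of U
# is enumerated (only valid without ties)
EXACT_N_MAX = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Uses the exact U distribution when n1 + n2 <= 12 and there are no
    ties, otherwise the normal approximation with tie correction and
    continuity correction. NaNs are dropped. Degenerate inputs (all
    values identical, or an empty group) give p = 1.

    Returns (U statistic of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return float("nan"), 1.0
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = stats.wilcoxon(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
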