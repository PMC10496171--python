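"""Generic rank-based comparisons shared across the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

MW_EXACT_N = 50        # exact Mann-Whitney null below this (no ties)
SPEARMAN_EXACT_N = 9   # exhaustive permutation null at or below this


@dataclass
class GroupComparison:
    statistic: float
    p: float
    method: str
    degenerate: bool = False


def mann_whitney(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test of a location shift between samples.

    Exact null for small samples without ties, else the normal
    approximation with tie correction. Identical constant samples are
    flagged degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return GroupComparison(statistic=x.size * y.size / 2.0, p=1.0,
                               method="mann_whitney", degenerate=True)
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size < MW_EXACT_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(statistic=float(res.statistic),
                           p=float(res.pvalue), method="mann_whitney")


def spearman(x, y) -> GroupComparison:
    """Spearman rank correlation with two-sided p.

    Exhaustive permutation null for n <= 9 (matching the exact small-sample
    distribution), else the t approximation. Zero rank variance gives NA.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return GroupComparison(statistic=np.nan, p=np.nan, method="spearman",
                               degenerate=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= SPEARMAN_EXACT_N:
        perms = np.array(list(permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt(np.sum(rx_c ** 2) * np.sum(ry_c ** 2))
        rhos = (rx_c[perms] @ ry_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        res = stats.spearmanr(x, y)
        p = float(res.pvalue)
    return GroupComparison(statistic=rho, p=p, method="spearman")
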