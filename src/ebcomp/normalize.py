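"""Library-composition normalization: TMM with singleton pairing, and
pairwise cyclic loess of log-expression."""

from __future__ import annotations

import itertools

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

TRIM_M = 0.30
TRIM_A = 0.05
MIN_SHARED = 50  # engage singleton pairing below this many shared genes


def _upper_quartile(col, lib):
    pos = col[col > 0]
    if pos.size == 0:
        return 0.0
    return np.quantile(pos / lib, 0.75)


def _pair_ma(ys, yr, ns, nr):
    """Trimmed, precision-weighted mean M of sample s against reference r.

    M/A are computed over genes positive in both samples; when fewer than
    ``MIN_SHARED`` shared genes exist, genes positive in exactly one sample
    are paired by decreasing magnitude and contribute pseudo-M values
    (singleton pairing).
    """
    shared = (ys > 0) & (yr > 0)
    ys_u, yr_u = ys[shared], yr[shared]
    if shared.sum() < MIN_SHARED:
        only_s = np.sort(ys[(ys > 0) & (yr == 0)])[::-1]
        only_r = np.sort(yr[(yr > 0) & (ys == 0)])[::-1]
        npair = min(only_s.size, only_r.size)
        if npair:
            ys_u = np.concatenate([ys_u, only_s[:npair]])
            yr_u = np.concatenate([yr_u, only_r[:npair]])
    if ys_u.size == 0:
        return 0.0
    ps, pr = ys_u / ns, yr_u / nr
    m = np.log2(ps / pr)
    a = 0.5 * np.log2(ps * pr)
    # asymptotic inverse variance of M (delta method)
    w = 1.0 / ((ns - ys_u) / (ns * ys_u) + (nr - yr_u) / (nr * yr_u))
    if np.max(np.abs(m)) < 1e-6:  # all ratios equal; no trimming needed
        return 0.0
    lo_m, hi_m = np.quantile(m, [TRIM_M, 1 - TRIM_M])
    lo_a, hi_a = np.quantile(a, [TRIM_A, 1 - TRIM_A])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        keep = np.ones_like(m, dtype=bool)
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def tmm_factors(counts) -> np.ndarray:
    """TMM-with-singleton-pairing size factors, geometric mean 1.

    The reference is the sample whose upper quartile (of positive counts
    over library size) is closest to the mean upper quartile. Each sample's
    factor is 2 to the precision-weighted mean M after trimming 30% of the
    M tails and 5% of the A tails.
    """
    y = np.asarray(counts, dtype=float)
    if hasattr(counts, "to_numpy"):
        y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    uq = np.array([_upper_quartile(y[:, j], lib[j]) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.array([_pair_ma(y[:, j], y[:, ref], lib[j], lib[ref])
                     for j in range(y.shape[1])])
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def cyclic_loess(logexpr, cycles: int = 3, frac: float = 0.7) -> np.ndarray:
    """Pairwise cyclic loess normalization of a gene x sample log matrix.

    Per cycle, for every sample pair the loess fit of M = x_i - x_j on
    A = (x_i + x_j)/2 is computed from the cycle's starting matrix, and half
    the fit is subtracted from i and added to j; all corrections of one
    cycle are applied together, which makes the result independent of the
    order in which samples are listed.
    """
    x = np.array(logexpr, dtype=float)
    if hasattr(logexpr, "to_numpy"):
        x = logexpr.to_numpy(dtype=float).copy()
    g, n = x.shape
    if n < 2:
        return x
    for _ in range(cycles):
        corr = np.zeros_like(x)
        for i, j in itertools.combinations(range(n), 2):
            m = x[:, i] - x[:, j]
            a = 0.5 * (x[:, i] + x[:, j])
            if np.allclose(m, 0.0, atol=1e-12):
                continue
            fit = lowess(m, a, frac=frac, it=1, return_sorted=False,
                         delta=0.01 * np.ptp(a))
            corr[:, i] -= fit / 2.0
            corr[:, j] += fit / 2.0
        x = x + corr / (n - 1)  # average the pairwise corrections per sample
        if np.max(np.abs(corr)) < 1e-10:
            break
    return x
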