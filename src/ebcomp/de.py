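"""Per-cell-type differential expression between species.

Pseudobulk counts are normalized (TMM + cyclic loess), given voom-style
precision weights, and fit per gene with a weighted linear mixed model:
species as a fixed effect (coded -1/2 human, +1/2 chimpanzee, so the
contrast is the full chimp-vs-human log2 fold change) and random intercepts
for individual and replicate, estimated by profiled REML. Residual
variances are shrunk by empirical-Bayes moderation before two-sided
t-tests; p-values are BH-adjusted within cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import scipy.special
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from . import normalize
from .preprocess import PseudobulkSet, filter_genes_expr

SPECIES_CODE = {"human": -0.5, "chimp": +0.5, "A": -0.5, "B": +0.5}


# --------------------------------------------------------------------------
# voom-style precision weights
# --------------------------------------------------------------------------

def log_cpm(counts, factors=None):
    """log2 counts per million with pseudocounts: log2((y+0.5)/(L*f+1)*1e6)."""
    y = counts.to_numpy(dtype=float) if hasattr(counts, "to_numpy") \
        else np.asarray(counts, dtype=float)
    lib = y.sum(axis=0)
    eff = lib * (np.ones(y.shape[1]) if factors is None else np.asarray(factors))
    return np.log2((y + 0.5) / (eff + 1.0) * 1e6), eff


def voom_weights(counts, factors, design, normalized_logcpm=None):
    """Precision weights from the fitted sqrt-sd vs log-count trend.

    Per gene, an OLS fit of log-cpm on the design yields the residual sd;
    a lowess of sqrt(sd) against mean log2 count gives the trend; each
    observation's weight is trend(fitted log-count)^-4, with predictions
    clipped to the fitted range. Returns (weights, logcpm). Pass
    ``normalized_logcpm`` (e.g. after cyclic loess) to fit the trend on the
    normalized values.
    """
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError("need more samples than model parameters")
    logcpm, eff = log_cpm(counts, factors)
    if normalized_logcpm is not None:
        logcpm = np.asarray(normalized_logcpm, dtype=float)
    beta, *_ = np.linalg.lstsq(x, logcpm.T, rcond=None)
    fitted = (x @ beta).T
    resid = logcpm - fitted
    s = np.sqrt((resid ** 2).sum(axis=1) / (n - p))
    mean_logcount = logcpm.mean(axis=1) + np.log2(np.exp(np.mean(np.log(eff + 1.0)))) - np.log2(1e6)
    sy = np.sqrt(s)
    if np.ptp(mean_logcount) < 1e-10:
        trend_x = np.array([mean_logcount[0]])
        trend_y = np.array([max(sy.mean(), 1e-6)])
    else:
        fit = lowess(sy, mean_logcount, frac=0.5, it=3)
        trend_x, trend_y = fit[:, 0], np.maximum(fit[:, 1], 1e-6)
    fitted_logcount = fitted + (np.log2(eff + 1.0) - np.log2(1e6))[None, :]
    fx = np.clip(fitted_logcount, trend_x[0], trend_x[-1])
    pred = np.interp(fx, trend_x, trend_y)
    w = pred ** -4.0
    return w, logcpm


# --------------------------------------------------------------------------
# weighted mixed model (profiled REML)
# --------------------------------------------------------------------------

@dataclass
class _MixedDesign:
    X: np.ndarray            # fixed design; column 1 is the species contrast
    A_list: list             # list of Z Z^T for each random factor
    factor_names: list       # parallel to A_list
    n: int
    p: int
    indiv_codes: np.ndarray | None = None
    indiv_species: np.ndarray | None = None  # per individual, +-1/2 coding


def build_design(sample_meta: pd.DataFrame, covariates=None) -> _MixedDesign:
    species = sample_meta["species"].map(SPECIES_CODE)
    if species.isna().any():
        raise ValueError("unrecognized species labels in sample metadata")
    cols = [np.ones(len(sample_meta)), species.to_numpy(dtype=float)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cov = cov[:, None] if cov.ndim == 1 else cov
        cols.extend(cov.T)
    x = np.column_stack(cols)
    a_list, names = [], []
    indiv_codes = indiv_species = None
    for key in ("individual", "replicate"):
        codes, uniq = pd.factorize(sample_meta[key])
        if len(uniq) > 1:
            z = np.zeros((len(codes), len(uniq)))
            z[np.arange(len(codes)), codes] = 1.0
            a_list.append(z @ z.T)
            names.append(key)
            if key == "individual":
                indiv_codes = codes
                sp = species.to_numpy(dtype=float)
                indiv_species = np.array(
                    [sp[codes == i].mean() for i in range(len(uniq))])
    return _MixedDesign(X=x, A_list=a_list, factor_names=names,
                        n=x.shape[0], p=x.shape[1],
                        indiv_codes=indiv_codes,
                        indiv_species=indiv_species)


ETA_MIN = -18.0  # log variance-ratio floor; effectively a zero component
_COARSE_ETA = np.array([-18.0, -4.0, -2.5, -1.5, -0.5, 1.0])
_ZOOM_LEVELS = 6


def _build_v(theta, d_inv, a_list):
    g, n = d_inv.shape
    v = np.zeros((g, n, n))
    idx = np.arange(n)
    v[:, idx, idx] = d_inv
    for t, a in zip(theta, a_list):
        v += t[:, None, None] * a[None, :, :]
    return v


def _batched_crit(theta, d_inv, a_list, x, y):
    """REML criterion for every gene at per-gene variance ratios.

    theta: (d, G) component variance ratios; d_inv: (G, n) weighted residual
    diagonals; y: (G, n). Returns (crit, beta, q, xtvx, vi_x) with batched
    factorizations across genes.
    """
    g, n = y.shape
    p = x.shape[1]
    v = _build_v(theta, d_inv, a_list)
    ell = np.linalg.cholesky(v)
    logdet_v = 2.0 * np.log(np.einsum("gii->gi", ell)).sum(axis=1)
    rhs = np.concatenate([np.broadcast_to(x, (g, n, p)), y[:, :, None]],
                         axis=2)
    vi_rhs = np.linalg.solve(v, rhs)
    vi_x, vi_y = vi_rhs[:, :, :p], vi_rhs[:, :, p]
    xtvx = np.einsum("np,gnq->gpq", x, vi_x)
    xtvy = np.einsum("np,gn->gp", x, vi_y)
    beta = np.linalg.solve(xtvx, xtvy[:, :, None])[:, :, 0]
    q = np.einsum("gn,gn->g", y, vi_y) - np.einsum("gp,gp->g", xtvy, beta)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    crit = (n - p) * np.log(np.maximum(q, 1e-300)) + logdet_v + logdet_x
    crit = np.where((q > 0) & (sign > 0), crit, np.inf)
    return crit, beta, q, xtvx, vi_x


def _satterthwaite_df(theta, sigma2, d_inv, a_list, x, xtvx, vi_x,
                      contrast_idx: int = 1):
    """Per-gene Satterthwaite degrees of freedom for the species contrast.

    Delta method on se^2 as a function of the variance components, with the
    REML expected information for their covariance: df = 2 se^4 / (g' I^-1 g).
    """
    g_n, n = d_inv.shape
    p = x.shape[1]
    v = _build_v(theta, d_inv, a_list)
    vinv = np.linalg.solve(v, np.broadcast_to(np.eye(n), (g_n, n, n)).copy())
    sigma_beta = np.linalg.inv(xtvx)  # per unit sigma^2
    # P = Vinv - Vinv X (X'VinvX)^-1 X'Vinv, all per unit sigma^2
    b = vi_x  # (g, n, p)
    pmat = vinv - np.einsum("gnp,gpq,gmq->gnm", b, sigma_beta, b)
    # variance-component design: V = sum_i gamma_i V_i with gamma_0 = sigma^2
    comp = [None] + list(a_list)  # comp 0 handled diagonally
    n_comp = 1 + len(a_list)
    pv = []
    for i in range(n_comp):
        if i == 0:
            pv.append(pmat * d_inv[:, None, :])
        else:
            pv.append(pmat @ comp[i])
    info = np.empty((g_n, n_comp, n_comp))
    for i in range(n_comp):
        for j in range(i, n_comp):
            tr = np.einsum("gnm,gmn->g", pv[i], pv[j])
            info[:, i, j] = info[:, j, i] = 0.5 * tr
    h = np.einsum("gnp,gp->gn", b, sigma_beta[:, :, contrast_idx])
    grad = np.empty((g_n, n_comp))
    grad[:, 0] = np.einsum("gn,gn->g", h * d_inv, h)
    for i in range(1, n_comp):
        grad[:, i] = np.einsum("gn,nm,gm->g", h, comp[i], h)
    # components estimated at the zero boundary carry no df charge: mask
    # their gradient and decouple them in the information matrix
    for i in range(1, n_comp):
        at_floor = theta[i - 1] <= 1e-7
        grad[at_floor, i] = 0.0
        info[at_floor, i, :] = 0.0
        info[at_floor, :, i] = 0.0
        info[at_floor, i, i] = 1.0
    se2 = sigma2 * sigma_beta[:, contrast_idx, contrast_idx]
    # absolute-scale gradient and information: gamma = sigma^2 * (1, theta)
    # se^2, P and V_i above are per unit sigma^2; the sigma^2 factors cancel
    # in df = 2 se^4 / (g' I^-1 g) when both are computed on the same scale.
    try:
        denom = np.einsum("gi,gij,gj->g",
                          grad, np.linalg.inv(info), grad)
    except np.linalg.LinAlgError:
        return np.full(g_n, float(n - p))
    se2_unit = sigma_beta[:, contrast_idx, contrast_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * se2_unit ** 2 / denom
    df = np.where(np.isfinite(df) & (df > 0), df, float(n - p))
    _ = se2
    return np.clip(df, 1.0, float(n - p))


def fit_mixed_de(logcpm, weights, sample_meta: pd.DataFrame, genes=None,
                 covariates=None) -> pd.DataFrame:
    """Per-gene weighted mixed-model species contrasts by profiled REML.

    The two variance ratios (individual, replicate; relative to the
    residual) are optimized per gene on a log-scale lattice: a coarse grid
    shared across genes, then per-gene 3^d zoom refinements down to a
    resolution of ~0.03 log units, all evaluated with batched Cholesky
    factorizations. Returns a DataFrame with raw log2fc, sigma (residual
    sd), se_unit (se / sigma), se, t, df, p; moderation and FDR are applied
    separately so the joint stage can reuse the raw fits.
    """
    des = build_design(sample_meta, covariates)
    if des.n - des.p < 1:
        raise ValueError("no residual degrees of freedom")
    y = np.atleast_2d(np.asarray(logcpm, dtype=float))
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    g = y.shape[0]
    if genes is None:
        genes = [f"g{i}" for i in range(g)]
    d_inv = 1.0 / w
    x, a_list = des.X, des.A_list
    nd = len(a_list)
    if nd == 0:
        eta_best = np.empty((0, g))
    else:
        import itertools as _it

        best_crit = np.full(g, np.inf)
        eta_best = np.zeros((nd, g))
        for combo in _it.product(_COARSE_ETA, repeat=nd):
            eta = np.tile(np.asarray(combo)[:, None], (1, g))
            crit, *_ = _batched_crit(np.exp(eta), d_inv, a_list, x, y)
            better = crit < best_crit
            best_crit = np.where(better, crit, best_crit)
            eta_best[:, better] = eta[:, better]
        step = 1.0
        offsets = np.array(list(_it.product((-1.0, 0.0, 1.0), repeat=nd))).T
        for _ in range(_ZOOM_LEVELS):
            for oi in range(offsets.shape[1]):
                if not np.any(offsets[:, oi]):
                    continue
                eta = np.clip(eta_best + step * offsets[:, oi][:, None],
                              ETA_MIN, 4.0)
                crit, *_ = _batched_crit(np.exp(eta), d_inv, a_list, x, y)
                better = crit < best_crit
                best_crit = np.where(better, crit, best_crit)
                eta_best[:, better] = eta[:, better]
            step /= 2.0
    theta = np.exp(eta_best)
    _, beta, q, xtvx, vi_x = _batched_crit(theta, d_inv, a_list, x, y)
    nfree = des.n - des.p
    sigma2 = np.maximum(q, 0.0) / nfree
    xtvx_inv = np.linalg.inv(xtvx)
    se_unit = np.sqrt(xtvx_inv[:, 1, 1])
    if nd:
        df_satt = _satterthwaite_df(theta, sigma2, d_inv, a_list, x,
                                    xtvx, vi_x)
    else:
        df_satt = np.full(g, float(nfree))
    out = pd.DataFrame({"gene": list(genes), "log2fc": beta[:, 1],
                        "sigma": np.sqrt(sigma2), "se_unit": se_unit})
    out["se"] = out["sigma"] * out["se_unit"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["t"] = out["log2fc"] / out["se"]
    out["df"] = df_satt
    out["df_resid"] = float(nfree)
    out["p"] = 2.0 * stats.t.sf(np.abs(out["t"]), df_satt)
    out["collapsed"] = False
    _apply_collapsed_fallback(out, des, theta, y, w, covariates)
    return out


def _apply_collapsed_fallback(out, des, theta, y, w, covariates):
    """Exact individual-level inference where REML hits the zero boundary.

    When the individual variance ratio collapses to zero, the REML SE
    reduces to the weighted-OLS one and understates the contrast variance,
    inflating extreme statistics. For those genes the species contrast is
    tested on weighted per-individual means with the pooled two-sample t
    (df = n_individuals - 2), which is exactly calibrated in the balanced
    crossed design (replicate effects cancel in the contrast). Skipped when
    fixed covariates are present.
    """
    if covariates is not None or "individual" not in des.factor_names:
        return
    idx = des.factor_names.index("individual")
    codes, isp = des.indiv_codes, des.indiv_species
    n_indiv = len(isp)
    human = np.isclose(isp, -0.5)
    chimp = np.isclose(isp, 0.5)
    nh, nc = int(human.sum()), int(chimp.sum())
    if nh < 2 or nc < 2 or not np.all(human | chimp):
        return
    at_floor = theta[idx] <= 1e-7
    if not at_floor.any():
        return
    yb, wb = y[at_floor], w[at_floor]
    means = np.stack([
        (wb[:, codes == i] * yb[:, codes == i]).sum(axis=1)
        / wb[:, codes == i].sum(axis=1)
        for i in range(n_indiv)], axis=1)
    mh, mc = means[:, human], means[:, chimp]
    contrast = mc.mean(axis=1) - mh.mean(axis=1)
    sp2 = ((mh.var(axis=1, ddof=1) * (nh - 1)
            + mc.var(axis=1, ddof=1) * (nc - 1)) / (nh + nc - 2))
    se = np.sqrt(np.maximum(sp2, 1e-300) * (1.0 / nh + 1.0 / nc))
    df = float(nh + nc - 2)
    out.loc[at_floor, "log2fc"] = contrast
    out.loc[at_floor, "se"] = se
    with np.errstate(divide="ignore", invalid="ignore"):
        out.loc[at_floor, "t"] = contrast / se
    out.loc[at_floor, "df"] = df
    out.loc[at_floor, "p"] = 2.0 * stats.t.sf(np.abs(contrast) / se, df)
    out.loc[at_floor, "collapsed"] = True


def fit_fixed_de(logcpm, weights, sample_meta: pd.DataFrame, genes=None,
                 covariates=None) -> pd.DataFrame:
    """Weighted fixed-effect (OLS) species contrasts, limma-voom style.

    Used by the joint (cormotif) stage, where per-condition moderated
    t-statistics come from fixed-effect fits.
    """
    des = build_design(sample_meta, covariates)
    x = des.X
    n, p = des.n, des.p
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    y = np.asarray(logcpm, dtype=float)
    w = np.asarray(weights, dtype=float)
    g = y.shape[0]
    if genes is None:
        genes = [f"g{i}" for i in range(g)]
    betas = np.empty(g)
    sigmas = np.empty(g)
    se_units = np.empty(g)
    for gi in range(g):
        wg = w[gi]
        xw = x * wg[:, None]
        xtwx = x.T @ xw
        xtwy = xw.T @ y[gi]
        xtwx_inv = np.linalg.inv(xtwx)
        beta = xtwx_inv @ xtwy
        resid = y[gi] - x @ beta
        rss = float(np.sum(wg * resid ** 2))
        sigmas[gi] = np.sqrt(rss / (n - p))
        betas[gi] = beta[1]
        se_units[gi] = np.sqrt(xtwx_inv[1, 1])
    out = pd.DataFrame({"gene": list(genes), "log2fc": betas, "sigma": sigmas,
                        "se_unit": se_units})
    out["se"] = out["sigma"] * out["se_unit"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["t"] = out["log2fc"] / out["se"]
    out["df"] = float(n - p)
    out["df_resid"] = float(n - p)
    out["p"] = 2.0 * stats.t.sf(np.abs(out["t"]), n - p)
    return out


# --------------------------------------------------------------------------
# empirical-Bayes moderation
# --------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = scipy.special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / scipy.special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(sigma2, df):
    """Method-of-moments prior (d0, s0^2) on log residual variances.

    Fits a scaled inverse-chi-square prior: e = log s^2 - psi(d/2) +
    log(d/2); var(e) in excess of trigamma(d/2) determines d0, the mean
    determines s0^2. Returns (d0, s0sq); d0 = inf when the observed spread
    is at or below the chi-square expectation (complete shrinkage).
    """
    s2 = np.asarray(sigma2, dtype=float)
    pos = np.isfinite(s2) & (s2 > 0)
    if pos.sum() < 10:
        raise ValueError("need >= 10 finite positive variances")
    z = np.log(s2[pos])
    e = z - scipy.special.psi(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(scipy.special.polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess spread over the chi-square expectation: complete
        # shrinkage to the common observed variance (geometric mean), so
        # identical variances stay exactly fixed
        return np.inf, float(np.exp(np.mean(z)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(np.mean(e) + scipy.special.psi(d0 / 2.0)
                        - np.log(d0 / 2.0)))
    return d0, s0sq


def moderate_stats(fit: pd.DataFrame) -> pd.DataFrame:
    """Shrink residual variances toward the fitted prior and recompute t.

    Posterior variance s~^2 = (d0 s0^2 + d s^2) / (d0 + d); moderated
    t = beta / (s~ * se_unit); df = d + d0. If the prior cannot be
    estimated, the fit is returned unmoderated with ``moderated=False``.
    """
    out = fit.copy()
    d = float(fit.get("df_resid", fit["df"]).iloc[0])
    try:
        d0, s0sq = estimate_variance_prior(fit["sigma"] ** 2, d)
    except ValueError:
        out["moderated"] = False
        return out
    s2 = out["sigma"].to_numpy() ** 2
    df_t = out["df"].to_numpy(dtype=float)  # Satterthwaite for mixed fits
    # Effective df of the moderated contrast variance s~^2 * u(theta):
    # pooling improves the residual part (d -> d + d0) but not the
    # random-effect-ratio part, whose uncertainty the Satterthwaite df
    # carries; combine on the log-variance scale:
    #   1/df_eff = 1/(d + d0) + 1/df_satt - 1/d
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        inv_df = 1.0 / df_t - 1.0 / d
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        inv_df = 1.0 / (d + d0) + 1.0 / df_t - 1.0 / d
    with np.errstate(divide="ignore"):
        df_post = np.where(inv_df > 0, 1.0 / np.maximum(inv_df, 1e-12),
                           np.inf)
    keep = (out["collapsed"].to_numpy(dtype=bool)
            if "collapsed" in out.columns else np.zeros(len(out), bool))
    old = (out.reindex(columns=["se", "t", "df", "p"]).to_numpy()
           if keep.any() else None)
    out["se"] = np.sqrt(s2_post) * out["se_unit"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["t"] = out["log2fc"] / out["se"]
    out["df"] = df_post
    out["p"] = np.where(
        np.isinf(df_post), 2.0 * stats.norm.sf(np.abs(out["t"])),
        2.0 * stats.t.sf(np.abs(out["t"]), np.where(np.isinf(df_post), 1.0,
                                                    df_post)))
    # genes tested by the exact collapsed fallback keep their inference
    if keep.any():
        out.loc[keep, ["se", "t", "df", "p"]] = old[keep]
    out["moderated"] = True
    out.attrs["d0"] = d0
    out.attrs["s0sq"] = s0sq
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaN p-values pass through as NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def prob_effect_in_bound(log2fc, se, df, bound: float = 0.5) -> np.ndarray:
    """P(-bound < effect < bound) from the t sampling distribution.

    F_t((bound - b)/se; df) - F_t((-bound - b)/se; df); with se = 0, returns
    the indicator |b| < bound.
    """
    scalar = np.ndim(log2fc) == 0 and np.ndim(se) == 0
    b = np.atleast_1d(np.asarray(log2fc, dtype=float))
    s = np.broadcast_to(np.asarray(se, dtype=float), b.shape).copy()
    d = np.broadcast_to(np.asarray(df, dtype=float), b.shape)
    zero = s == 0
    s[zero] = 1.0
    upper = stats.t.cdf((bound - b) / s, d)
    lower = stats.t.cdf((-bound - b) / s, d)
    out = upper - lower
    out[zero] = (np.abs(b[zero]) < bound).astype(float)
    out = np.where(np.isfinite(b) & np.isfinite(np.atleast_1d(
        np.asarray(se, dtype=float))), out, np.nan)
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# one-call cell-type DE
# --------------------------------------------------------------------------

def de_for_celltype(pb_ct: PseudobulkSet, min_count: int = 5,
                    covariates=None, moderate: bool = True,
                    mixed: bool = True) -> pd.DataFrame:
    """Filter, normalize, weight and fit one cell type's pseudobulk.

    Returns the per-gene DE table with columns gene, log2fc, se, t, df, p,
    fdr. ``mixed=False`` switches to the fixed-effect (voom/limma-style)
    fit used for the joint analysis.
    """
    genes = filter_genes_expr(pb_ct, min_count=min_count)
    counts = pb_ct.counts.loc[genes]
    factors = normalize.tmm_factors(counts)
    des = build_design(pb_ct.sample_meta, covariates)
    raw_logcpm, _ = log_cpm(counts, factors)
    logcpm = normalize.cyclic_loess(raw_logcpm)
    w, _ = voom_weights(counts, factors, des.X, normalized_logcpm=logcpm)
    fitter = fit_mixed_de if mixed else fit_fixed_de
    fit = fitter(logcpm, w, pb_ct.sample_meta, genes=genes,
                 covariates=covariates)
    if moderate:
        fit = moderate_stats(fit)
    fit["fdr"] = bh_adjust(fit["p"])
    return fit
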