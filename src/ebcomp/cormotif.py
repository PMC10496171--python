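"""Joint differential expression across cell types via correlation motifs.

Per-cell-type moderated t-statistics (from count input: voom precision
weights + fixed-effect species fits + empirical-Bayes moderation) feed a
K-motif mixture model: each motif k is a vector q_k of per-cell-type DE
probabilities, genes belong softly to motifs, and the null/alternative
densities of t are the central t and an equal-weight scale mixture of
widened t densities. EM yields motif assignments and per-gene x cell-type
posterior DE probabilities, which drive the conserved-gene and
tissue-restricted-DE classifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp

from . import de as _de
from .preprocess import PseudobulkSet

V_GRID = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


@dataclass
class TStatMatrix:
    """Gene x cell-type moderated t-statistics with per-cell-type df."""

    t: pd.DataFrame              # genes x celltypes; NaN where filtered out
    df: pd.Series                # per cell type
    fits: dict = field(default_factory=dict)  # cell type -> DE table


def condition_tstats(pb: PseudobulkSet, celltypes=None, min_count: int = 5) -> TStatMatrix:
    """Per-cell-type t and df under the same filters/normalizations as the
    single-cell-type DE (genes filtered out in a cell type are NaN)."""
    if celltypes is None:
        celltypes = sorted(pb.sample_meta["cell_type"].unique())
    cols, dfs, fits = {}, {}, {}
    for ct in celltypes:
        sub = pb.subset_celltype(ct)
        n_sp = sub.sample_meta.groupby("species").size()
        if len(n_sp) < 2 or (n_sp < 2).any():
            continue
        fit = _de.de_for_celltype(sub, min_count=min_count, mixed=False)
        fits[ct] = fit
        cols[ct] = fit.set_index("gene")["t"]
        dfs[ct] = float(fit["df"].iloc[0])
    if not cols:
        raise ValueError("no cell type had >= 2 samples per species")
    t = pd.DataFrame(cols)
    t = t.loc[sorted(t.index)]
    return TStatMatrix(t=t, df=pd.Series(dfs), fits=fits)


@dataclass
class MotifModel:
    """Fitted K-motif mixture."""

    K: int
    Q: np.ndarray                 # K x C DE probabilities
    pi: np.ndarray                # K mixing weights
    loglik: float
    bic: float
    gene_motif_post: pd.DataFrame  # G x K responsibilities
    de_post: pd.DataFrame          # G x C posterior DE probabilities
    loglik_trace: list = field(default_factory=list)
    bic_by_k: dict = field(default_factory=dict)

    @property
    def genes(self):
        return list(self.de_post.index)

    @property
    def celltypes(self):
        return list(self.de_post.columns)


def _log_densities(t: pd.DataFrame, df: pd.Series, v_grid):
    """(log f0, log f1) per gene x cell type; NaN cells get 0 (neutral)."""
    tv = t.to_numpy(dtype=float)
    obs = np.isfinite(tv)
    g, c = tv.shape
    lf0 = np.zeros((g, c))
    lf1 = np.zeros((g, c))
    v = np.asarray(v_grid, dtype=float)
    for j, ct in enumerate(t.columns):
        d = float(df[ct])
        x = tv[obs[:, j], j]
        lf0[obs[:, j], j] = stats.t.logpdf(x, d)
        comp = np.stack([
            -0.5 * np.log1p(vi) + stats.t.logpdf(x / np.sqrt(1.0 + vi), d)
            for vi in v
        ])
        lf1[obs[:, j], j] = logsumexp(comp, axis=0) - np.log(len(v))
    return lf0, lf1, obs


def _em_once(lf0, lf1, obs, k, rng, tol, max_iter):
    g, c = lf0.shape
    # e = f1/f0 per gene x cell type; 1 (neutral) where unobserved, so the
    # per-condition mixture factor a = (1-q) + q e is automatically 1 there
    e = np.exp(np.clip(lf1 - lf0, -500.0, 500.0))
    e = np.where(obs, e, 1.0)
    lf0row = np.where(obs, lf0, 0.0).sum(axis=1)
    q = rng.uniform(0.05, 0.95, (k, c))
    pi = np.full(k, 1.0 / k)
    prev = -np.inf
    trace = []
    for _ in range(max_iter):
        qe = q[None, :, :] * e[:, None, :]          # (G, K, C)
        a = (1.0 - q)[None, :, :] + qe
        lr = (np.log(np.clip(pi, 1e-300, 1.0))[None, :]
              + np.log(a).sum(axis=2))
        norm = logsumexp(lr, axis=1)
        loglik = float((norm + lf0row).sum())
        r = np.exp(lr - norm[:, None])
        p_de = qe / a                                # within-motif DE posterior
        rw = r[:, :, None] * obs[:, None, :]
        denom = rw.sum(axis=0)
        q = np.where(denom > 0,
                     (rw * p_de).sum(axis=0) / np.maximum(denom, 1e-300), q)
        pi = r.mean(axis=0)
        trace.append(loglik)
        if loglik + 1e-8 * max(1.0, abs(loglik)) < prev:
            raise RuntimeError("EM log-likelihood decreased")
        if abs(loglik - prev) < tol:
            break
        prev = loglik
    # final E-step so the returned responsibilities, posteriors and
    # log-likelihood are consistent with the returned (q, pi)
    qe = q[None, :, :] * e[:, None, :]
    a = (1.0 - q)[None, :, :] + qe
    lr = (np.log(np.clip(pi, 1e-300, 1.0))[None, :] + np.log(a).sum(axis=2))
    norm = logsumexp(lr, axis=1)
    loglik = float((norm + lf0row).sum())
    trace.append(loglik)
    r = np.exp(lr - norm[:, None])
    p_de = qe / a
    de_post = (r[:, :, None] * p_de).sum(axis=1)
    de_post = np.where(obs, de_post, np.nan)
    return q, pi, loglik, r, de_post, trace


def fit_cormotif_em(tstats: TStatMatrix, K: int, v_grid=V_GRID,
                    n_starts: int = 10, tol: float = 1e-6,
                    max_iter: int = 500, seed: int = 0) -> MotifModel:
    """Fit the K-motif mixture by EM; best of ``n_starts`` random restarts.

    The log-likelihood is asserted non-decreasing at every iteration.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    g = tstats.t.shape[0]
    if g < 10 * K:
        raise ValueError(f"need >= {10 * K} genes to fit K={K}")
    lf0, lf1, obs = _log_densities(tstats.t, tstats.df, v_grid)
    best = None
    failures = []
    for s in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, K, s]))
        try:
            res = _em_once(lf0, lf1, obs, K, rng, tol, max_iter)
        except (RuntimeError, FloatingPointError) as exc:
            failures.append(exc)
            continue
        if best is None or res[2] > best[2]:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} EM restarts failed: {failures[-1]}")
    q, pi, loglik, r, de_post, trace = best
    c = lf0.shape[1]
    bic = -2.0 * loglik + (K - 1 + K * c) * np.log(g)
    return MotifModel(
        K=K, Q=q, pi=pi, loglik=loglik, bic=bic,
        gene_motif_post=pd.DataFrame(r, index=tstats.t.index,
                                     columns=[f"motif{k}" for k in range(K)]),
        de_post=pd.DataFrame(de_post, index=tstats.t.index,
                             columns=tstats.t.columns),
        loglik_trace=trace)


def select_k_bic(tstats: TStatMatrix, K_range, **kwargs) -> MotifModel:
    """Fit every K in ``K_range`` and return the minimum-BIC model."""
    ks = list(K_range)
    if not ks:
        raise ValueError("K_range must be non-empty")
    models, errors = {}, {}
    for k in ks:
        try:
            models[k] = fit_cormotif_em(tstats, k, **kwargs)
        except (ValueError, RuntimeError) as exc:
            errors[k] = exc
    if not models:
        raise RuntimeError(f"no K could be fitted: {errors}")
    best_k = min(models, key=lambda k: models[k].bic)
    best = models[best_k]
    best.bic_by_k = {k: m.bic for k, m in models.items()}
    return best


def classify_de(model: MotifModel, threshold: float = 0.95):
    """DE calls at the posterior threshold; returns (calls G x C boolean,
    per-gene count of DE cell types)."""
    calls = model.de_post >= threshold
    calls = calls.fillna(False)
    return calls, calls.sum(axis=1)


@dataclass
class ConservedSets:
    never_de: list          # set A: zero DE calls + well expressed
    effect_bounded: list    # set B: |effect| > bound never at >= conf
    conserved: list         # intersection


def classify_conserved(model: MotifModel, species_umi: dict, de_fits: dict,
                       threshold: float = 0.95, min_umi: int = 100,
                       min_celltypes: int = 10, bound: float = 0.5,
                       conf: float = 0.95) -> ConservedSets:
    """Conserved genes: never DE, well expressed in both species, and never
    confidently exceeding the effect bound.

    ``species_umi``: species -> genes x celltypes pseudobulk UMI totals.
    ``de_fits``: cell type -> mixed-model DE table (for the effect-bound
    probability).
    """
    calls, n_de = classify_de(model, threshold)
    genes = model.de_post.index
    ok_expr = pd.Series(True, index=genes)
    for umi in species_umi.values():
        aligned = umi.reindex(index=genes).fillna(0)
        ok_expr &= (aligned >= min_umi).sum(axis=1) >= min_celltypes
    set_a = sorted(genes[(n_de == 0) & ok_expr])
    exceed = pd.Series(False, index=genes)
    for fit in de_fits.values():
        f = fit.set_index("gene")
        p_out = 1.0 - _de.prob_effect_in_bound(
            f["log2fc"].to_numpy(), f["se"].to_numpy(),
            f["df"].to_numpy(), bound=bound)
        flag = pd.Series(p_out >= conf, index=f.index)
        exceed |= flag.reindex(genes, fill_value=False).astype(bool)
    set_b = sorted(genes[~exceed])
    return ConservedSets(never_de=set_a, effect_bounded=set_b,
                         conserved=sorted(set(set_a) & set(set_b)))


def find_restricted_de(model: MotifModel, species_umi: dict,
                       hi: float = 0.95, lo: float = 0.05,
                       min_umi: int = 100) -> pd.DataFrame:
    """Genes confidently DE in >= 1 cell type and confidently non-DE in >= 1
    well-expressed cell type (>= min_umi UMIs in that cell type in both
    species)."""
    genes = model.de_post.index
    cts = model.de_post.columns
    well = pd.DataFrame(True, index=genes, columns=cts)
    for umi in species_umi.values():
        well &= umi.reindex(index=genes, columns=cts).fillna(0) >= min_umi
    de_mask = model.de_post > hi
    cons_mask = (model.de_post < lo) & well
    rows = []
    for gene in genes:
        de_cts = list(cts[de_mask.loc[gene].fillna(False)])
        cons_cts = list(cts[cons_mask.loc[gene].fillna(False)])
        if de_cts and cons_cts:
            rows.append({"gene": gene,
                         "de_celltypes": ",".join(map(str, de_cts)),
                         "conserved_celltypes": ",".join(map(str, cons_cts))})
    return pd.DataFrame(rows, columns=["gene", "de_celltypes",
                                       "conserved_celltypes"])


def cormotif_cell_scores(residuals: pd.DataFrame, model: MotifModel):
    """Per-cell motif scores: membership-weighted residual sums, z-scored.

    score_ck = sum_g m_gk R_cg over the shared gene axis; z-scores are taken
    across cells per motif. Motifs with zero score variance are reported as
    all-zero with a flag. Returns (scores DataFrame cells x motifs, flags).
    """
    shared = residuals.columns.intersection(model.gene_motif_post.index)
    if len(shared) == 0:
        raise ValueError("residuals and model share no genes")
    r = residuals[shared].to_numpy(dtype=float)
    m = model.gene_motif_post.loc[shared].to_numpy(dtype=float)
    raw = r @ m
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    degenerate = sd < 1e-12
    z = np.zeros_like(raw)
    okc = ~degenerate
    z[:, okc] = (raw[:, okc] - mu[okc]) / sd[okc]
    scores = pd.DataFrame(z, index=residuals.index,
                          columns=model.gene_motif_post.columns)
    flags = pd.Series(degenerate, index=model.gene_motif_post.columns,
                      name="degenerate")
    return scores, flags


def match_motifs(q_est: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Permutation of estimated motifs best matching the true ones
    (Hungarian assignment on mean |Delta q|); returns row order for q_est."""
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(q_est[:, None, :] - q_true[None, :, :]).mean(axis=2)
    rows, cols = linear_sum_assignment(cost)
    order = np.empty(len(rows), dtype=int)
    order[cols] = rows
    return order
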