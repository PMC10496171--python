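"""Cis/trans decomposition of inter-species expression divergence.

In a tetraploid hybrid cell both species' alleles share one trans
environment, so the allelic log2 fold change isolates cis-regulatory
divergence. Per gene and cell type the cis component is |hybrid logFC|, the
trans (and non-genetic) component |diploid logFC - hybrid logFC|, and the
cis proportion their ratio:

    cis = |hybrid.logFC| / (|hybrid.logFC| + |diploid.logFC - hybrid.logFC|)

Genes are classed cis (mean cis proportion over DE cell types > 0.75),
trans (< 0.25), or intermediate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .de import bh_adjust

EXACT_N_MAX = 50  # exact signed-rank null below this (and without ties)


def _paired_wilcoxon_one(d: np.ndarray):
    d = d[d != 0]  # zero differences carry no sign information
    n = d.size
    if n == 0:
        return np.nan, np.nan
    absd = np.abs(d)
    ties = np.unique(absd).size < n
    if n < EXACT_N_MAX and not ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=True)
    return float(res.statistic), float(res.pvalue)


def hybrid_paired_wilcoxon(human, chimp, cell_meta: pd.DataFrame,
                           cell_type: str, genes=None) -> pd.DataFrame:
    """Per-gene paired Wilcoxon signed-rank test of within-cell allele
    differences (human minus chimp) for one cell type.

    Exact null when fewer than 50 informative cells and no tied magnitudes,
    else the normal approximation with continuity correction. All-zero
    differences give p = NA with a ``no_information`` flag. BH adjustment is
    within the cell type.
    """
    mask = (cell_meta["cell_type"] == cell_type).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 cells of {cell_type!r}")
    h = np.asarray(sp.csr_matrix(human)[mask].todense(), dtype=float)
    c = np.asarray(sp.csr_matrix(chimp)[mask].todense(), dtype=float)
    d = h - c
    rows = []
    for j in range(d.shape[1]):
        stat, p = _paired_wilcoxon_one(d[:, j])
        rows.append((stat, p))
    out = pd.DataFrame(rows, columns=["statistic", "p"])
    out.insert(0, "gene", list(genes) if genes is not None
               else [f"g{j}" for j in range(d.shape[1])])
    out["no_information"] = out["p"].isna()
    out["fdr"] = bh_adjust(out["p"])
    return out


def hybrid_logfc(human, chimp, cell_meta: pd.DataFrame, cell_type: str,
                 genes=None, pseudocount: float = 0.5) -> pd.Series:
    """Allelic pseudobulk log2 fold change (chimp over human) per gene.

    Each allele matrix is scaled by its total allele library (the ratio of
    totals enters as a global offset), then
    log2((sum chimp + 0.5) / (sum human + 0.5)) over the cell type's cells.
    Sign convention matches the diploid fits (chimp vs human).
    """
    h_all = sp.csr_matrix(human)
    c_all = sp.csr_matrix(chimp)
    lib_h = h_all.sum()
    lib_c = c_all.sum()
    mask = (cell_meta["cell_type"] == cell_type).to_numpy()
    h = np.asarray(h_all[mask].sum(axis=0)).ravel()
    c = np.asarray(c_all[mask].sum(axis=0)).ravel()
    lfc = (np.log2(c + pseudocount) - np.log2(h + pseudocount)
           - np.log2(lib_c / lib_h))
    idx = list(genes) if genes is not None else range(len(lfc))
    return pd.Series(lfc, index=idx, name="hybrid_log2fc")


def cis_proportion(hybrid_log2fc, diploid_log2fc):
    """|hybrid| / (|hybrid| + |diploid - hybrid|); NA when both terms are 0
    or either input is non-finite."""
    h = np.asarray(hybrid_log2fc, dtype=float)
    d = np.asarray(diploid_log2fc, dtype=float)
    cis = np.abs(h)
    trans = np.abs(d - h)
    denom = cis + trans
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, cis / np.where(denom > 0, denom, 1.0), np.nan)
    out = np.where(np.isfinite(h) & np.isfinite(d), out, np.nan)
    return out if out.shape else float(out)


def build_estimates(hybrid_fc: pd.DataFrame, diploid_fc: pd.DataFrame,
                    diploid_se: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long per-gene x cell-type table of cis/trans components.

    Inputs are genes x celltypes frames of hybrid and diploid log2FCs (and
    optionally the diploid SEs, used by the lowest-SE restriction).
    """
    cts = [c for c in hybrid_fc.columns if c in diploid_fc.columns]
    rows = []
    for ct in cts:
        joined = pd.DataFrame({"hybrid_log2fc": hybrid_fc[ct],
                               "diploid_log2fc": diploid_fc[ct]}).dropna()
        est = pd.DataFrame({
            "gene": joined.index,
            "cell_type": ct,
            "hybrid_log2fc": joined["hybrid_log2fc"].to_numpy(),
            "diploid_log2fc": joined["diploid_log2fc"].to_numpy(),
        })
        est["cis_component"] = np.abs(est["hybrid_log2fc"])
        est["trans_component"] = np.abs(est["diploid_log2fc"]
                                        - est["hybrid_log2fc"])
        est["cis_proportion"] = cis_proportion(est["hybrid_log2fc"],
                                               est["diploid_log2fc"])
        if diploid_se is not None:
            est["diploid_se"] = diploid_se[ct].reindex(joined.index).to_numpy()
        rows.append(est)
    return pd.concat(rows, ignore_index=True)


CLASS_CIS, CLASS_TRANS, CLASS_INTER, CLASS_UNDEF = (
    "cis", "trans", "intermediate", "undefined")


def classify_cis_trans(estimates: pd.DataFrame, de_calls: pd.DataFrame,
                       hi: float = 0.75, lo: float = 0.25) -> pd.DataFrame:
    """Per-gene class from the mean cis proportion over DE cell types.

    cis if mean > hi, trans if mean < lo, else intermediate; genes DE
    nowhere (or with no defined cis proportion in a DE cell type) are
    undefined. ``de_calls``: genes x celltypes boolean (joint-DE posterior
    calls).
    """
    est = estimates.copy()
    is_de = [
        bool(de_calls.at[g, ct]) if (g in de_calls.index
                                     and ct in de_calls.columns) else False
        for g, ct in zip(est["gene"], est["cell_type"])
    ]
    est = est[np.asarray(is_de) & est["cis_proportion"].notna()]
    mean_cis = est.groupby("gene")["cis_proportion"].mean()
    out = pd.DataFrame({"gene": de_calls.index})
    out["mean_cis_proportion"] = out["gene"].map(mean_cis)
    def _cls(v):
        if np.isnan(v):
            return CLASS_UNDEF
        if v > hi:
            return CLASS_CIS
        if v < lo:
            return CLASS_TRANS
        return CLASS_INTER
    out["cis_trans_class"] = out["mean_cis_proportion"].map(_cls)
    return out


def lowest_se_subset(estimates: pd.DataFrame, n: int = 1000):
    """The n gene x cell-type tests with the smallest diploid-fit SE.

    Ties break deterministically by (gene, cell type). Returns
    (subset frame, subset mean cis proportion, global mean cis proportion).
    """
    est = estimates.dropna(subset=["cis_proportion", "diploid_se"])
    if n > len(est):
        raise ValueError(f"n={n} exceeds the {len(est)} available tests")
    ranked = est.sort_values(["diploid_se", "gene", "cell_type"],
                             kind="mergesort")
    subset = ranked.head(n)
    return (subset, float(subset["cis_proportion"].mean()),
            float(est["cis_proportion"].mean()))
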