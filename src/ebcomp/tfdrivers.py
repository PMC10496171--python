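"""Transcription factors putatively driving trans differential expression.

Genes whose divergence is mostly trans (mean trans proportion > 75% over
their DE cell types) are tested for promoter-motif enrichment
(hypergeometric, BH across motifs); TFs binding enriched motifs that are
themselves DE somewhere and expressed in >= 3 cell types are then
correlated with their targets' DE patterns (Pearson over per-cell-type
log2FCs), with per-TF significance by Fisher's combination of the target
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust


def define_trans_de_set(estimates: pd.DataFrame, de_calls: pd.DataFrame,
                        trans_cut: float = 0.75) -> list:
    """Genes with mean trans proportion (1 - cis proportion) strictly above
    ``trans_cut`` across the cell types where they are DE."""
    est = estimates.copy()
    is_de = [
        bool(de_calls.at[g, ct]) if (g in de_calls.index
                                     and ct in de_calls.columns) else False
        for g, ct in zip(est["gene"], est["cell_type"])
    ]
    est = est[np.asarray(is_de) & est["cis_proportion"].notna()]
    mean_trans = 1.0 - est.groupby("gene")["cis_proportion"].mean()
    return sorted(mean_trans.index[mean_trans > trans_cut])


def hypergeom_enrichment_p(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail hypergeometric P(X >= k) of drawing k of big_k marked
    items in n draws from a universe of big_n."""
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def motif_enrichment(trans_set, annotations: dict, universe) -> pd.DataFrame:
    """Hypergeometric enrichment of each motif's target set in the trans-DE
    set, targets first intersected with the tested-gene universe; BH across
    motifs. Motifs with no in-universe targets are skipped.
    """
    universe = set(universe)
    trans = set(trans_set) & universe
    rows = []
    for motif_id in sorted(annotations):
        targets = set(annotations[motif_id]["targets"]) & universe
        if not targets:
            continue
        k = len(targets & trans)
        p = hypergeom_enrichment_p(k, len(targets), len(trans), len(universe))
        rows.append({"motif_id": motif_id, "overlap": k,
                     "set_size": len(targets), "draws": len(trans),
                     "universe": len(universe), "p": p})
    out = pd.DataFrame(rows, columns=["motif_id", "overlap", "set_size",
                                      "draws", "universe", "p"])
    out["fdr"] = bh_adjust(out["p"]) if len(out) else np.nan
    return out


def filter_candidate_tfs(enriched_motifs, annotations: dict,
                         de_celltype_counts: pd.Series,
                         expressed_counts: pd.Series,
                         min_expressed: int = 3) -> list:
    """TFs of enriched motifs that are DE in >= 1 cell type and pass the
    expression filter in >= ``min_expressed`` cell types."""
    tfs = set()
    for motif_id in enriched_motifs:
        tfs |= set(annotations[motif_id]["tfs"])
    out = []
    for tf in sorted(tfs):
        de_n = int(de_celltype_counts.get(tf, 0))
        expr_n = int(expressed_counts.get(tf, 0))
        if de_n >= 1 and expr_n >= min_expressed:
            out.append(tf)
    return out


def fisher_combine(pvalues) -> tuple[float, float]:
    """Fisher's method: statistic -2 sum ln p, chi-square with 2m df."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return np.nan, np.nan
    stat = float(-2.0 * np.sum(np.log(np.clip(p, 1e-300, 1.0))))
    return stat, float(stats.chi2.sf(stat, 2 * p.size))


@dataclass
class DriverResult:
    tf: str
    target_table: pd.DataFrame        # target, r, p per correlated target
    fisher_stat: float
    fisher_p: float
    n_targets: int
    skipped: list = field(default_factory=list)


def correlate_tf_targets(tf: str, targets, logfc: pd.DataFrame,
                         de_celltype_counts: pd.Series,
                         min_shared: int = 3) -> DriverResult:
    """Pearson correlation of the TF's per-cell-type log2FC pattern with
    each DE target's, plus Fisher-combined significance.

    ``logfc``: genes x celltypes fitted log2 fold changes. Targets not DE
    anywhere, or sharing fewer than ``min_shared`` finite cell types with
    the TF, are skipped (recorded in ``skipped``).
    """
    if tf not in logfc.index:
        raise ValueError(f"TF {tf!r} has no fitted log2FC pattern")
    tf_vec = logfc.loc[tf]
    rows, skipped = [], []
    for target in targets:
        if target == tf:
            continue
        if int(de_celltype_counts.get(target, 0)) < 1:
            skipped.append((target, "not-DE"))
            continue
        if target not in logfc.index:
            skipped.append((target, "no-logfc"))
            continue
        pair = pd.DataFrame({"tf": tf_vec, "tg": logfc.loc[target]}).dropna()
        if len(pair) < min_shared:
            skipped.append((target, "too-few-shared-celltypes"))
            continue
        if pair["tf"].std() == 0 or pair["tg"].std() == 0:
            skipped.append((target, "zero-variance"))
            continue
        r, p = stats.pearsonr(pair["tf"], pair["tg"])
        rows.append({"target": target, "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows, columns=["target", "r", "p"])
    stat, p_comb = fisher_combine(table["p"]) if len(table) else (np.nan, np.nan)
    return DriverResult(tf=tf, target_table=table, fisher_stat=stat,
                        fisher_p=p_comb, n_targets=len(table), skipped=skipped)


def driver_scan(candidate_tfs, annotations: dict, logfc: pd.DataFrame,
                de_celltype_counts: pd.Series,
                nominal_p: float = 0.05, target_fdr: float = 0.10) -> pd.DataFrame:
    """Run the TF-target correlation for every candidate TF; BH across TFs.

    Reports, per TF, the Fisher statistic/p/fdr and the counts of targets
    correlated at nominal p <= 0.05 and at target-level BH fdr <= 0.10
    (the two thresholds reported separately).
    """
    tf_of_motif = {}
    for motif_id, ann in annotations.items():
        for tf in ann["tfs"]:
            tf_of_motif.setdefault(tf, set()).update(ann["targets"])
    rows, all_target_tables = [], []
    for tf in candidate_tfs:
        targets = sorted(tf_of_motif.get(tf, set()))
        res = correlate_tf_targets(tf, targets, logfc, de_celltype_counts)
        rows.append({"tf": tf, "fisher_stat": res.fisher_stat,
                     "fisher_p": res.fisher_p, "n_targets": res.n_targets,
                     "n_nominal": int((res.target_table["p"] <= nominal_p).sum())
                     if res.n_targets else 0})
        if res.n_targets:
            t = res.target_table.copy()
            t.insert(0, "tf", tf)
            all_target_tables.append(t)
    out = pd.DataFrame(rows, columns=["tf", "fisher_stat", "fisher_p",
                                      "n_targets", "n_nominal"])
    out["fisher_fdr"] = bh_adjust(out["fisher_p"]) if len(out) else np.nan
    if all_target_tables:
        tt = pd.concat(all_target_tables, ignore_index=True)
        tt["fdr"] = bh_adjust(tt["p"])
        n_fdr = tt[tt["fdr"] <= target_fdr].groupby("tf").size()
        out["n_target_fdr"] = out["tf"].map(n_fdr).fillna(0).astype(int)
        out.attrs["target_table"] = tt
    else:
        out["n_target_fdr"] = 0
    return out


def load_motif_annotations(path) -> dict:
    """Read a motif TSV (motif_id, target_gene, tf_gene) into the dict form
    the enrichment and driver functions consume."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for motif_id, sub in df.groupby("motif_id"):
        out[str(motif_id)] = {"targets": set(sub["target_gene"].astype(str)),
                              "tfs": set(sub["tf_gene"].astype(str))}
    return out
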