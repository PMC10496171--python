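"""Cell-level preprocessing: species assignment, QC, label transfer,
pseudobulk aggregation, cell-type/gene filters and composition PCs.

Species are assigned per barcode from per-genome uniquely-mapping read
counts (> 90% rule); droplets are filtered on genes detected and
mitochondrial fraction; labels come from nearest-centroid transfer in a
reference embedding; pseudobulk sums cells by individual x replicate x cell
type, dropping samples with five or fewer cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

SPECIES_A, SPECIES_B, UNASSIGNED = "A", "B", "unassigned"


def assign_species(reads_a, reads_b, purity: float = 0.9):
    """Assign species A/B/unassigned from per-genome read counts.

    A barcode is assigned to a species iff strictly more than ``purity``
    (default 90%) of its uniquely mapping reads hit that genome. Zero total
    reads -> unassigned.
    """
    a = np.atleast_1d(np.asarray(reads_a, dtype=float))
    b = np.atleast_1d(np.asarray(reads_b, dtype=float))
    total = a + b
    out = np.full(a.shape, UNASSIGNED, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, a / np.where(total > 0, total, 1.0), np.nan)
    out[(total > 0) & (frac > purity)] = SPECIES_A
    out[(total > 0) & (1.0 - frac > purity)] = SPECIES_B
    if np.isscalar(reads_a) or np.asarray(reads_a).ndim == 0:
        return out.item()
    return out


def qc_filter_cells(meta: pd.DataFrame, min_genes: int = 1000,
                    mito_low: float = 0.001, mito_high: float = 0.2) -> pd.Series:
    """Boolean keep mask: genes_detected >= min_genes and mito fraction
    within [mito_low, mito_high] (droplets strictly outside are dropped).

    Defaults are the diploid thresholds (1000, 0.1%, 20%); hybrid libraries
    use ``min_genes=2000``.
    """
    if not (0 <= mito_low < mito_high <= 1):
        raise ValueError("require 0 <= mito_low < mito_high <= 1")
    return ((meta["genes_detected"] >= min_genes)
            & (meta["mito_fraction"] >= mito_low)
            & (meta["mito_fraction"] <= mito_high))


def assign_labels(centroids: dict, coords) -> pd.Series:
    """Nearest-centroid label transfer by Euclidean distance.

    Ties break to the lexicographically smallest label. ``coords`` is a
    barcode x dim DataFrame (or array); centroid vectors must share its
    dimension.
    """
    if not centroids:
        raise ValueError("centroids must be non-empty")
    labels = sorted(centroids)
    cmat = np.vstack([np.asarray(centroids[lab], dtype=float) for lab in labels])
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != cmat.shape[1]:
        raise ValueError(
            f"embedding dimension mismatch: cells {x.shape[1]}, "
            f"centroids {cmat.shape[1]}")
    nearest = np.argmin(cdist(x, cmat), axis=1)  # argmin -> first == smallest
    idx = coords.index if isinstance(coords, pd.DataFrame) else None
    return pd.Series([labels[i] for i in nearest], index=idx, name="label")


@dataclass
class PseudobulkSet:
    """Gene x sample UMI sums with sample metadata.

    ``counts``: genes x samples integer DataFrame; ``sample_meta``: per
    retained sample (species, individual, replicate, cell_type, n_cells);
    ``group_sizes``: cell counts of ALL groups, including the ones dropped
    for having five or fewer cells (needed by the cell-type filter).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    group_sizes: pd.DataFrame

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_celltype(self, cell_type: str) -> "PseudobulkSet":
        keep = self.sample_meta["cell_type"] == cell_type
        return PseudobulkSet(self.counts.loc[:, keep.values],
                             self.sample_meta.loc[keep],
                             self.group_sizes)


def make_pseudobulk(counts, meta: pd.DataFrame, genes,
                    min_cells: int = 6) -> PseudobulkSet:
    """Sum cells into individual x replicate x cell type pseudobulk samples.

    Groups with fewer than ``min_cells`` cells (default: five or fewer) are
    dropped from the counts but kept in ``group_sizes``.
    """
    keys = ["species", "individual", "replicate", "cell_type"]
    for k in keys:
        if k not in meta.columns:
            raise ValueError(f"cell metadata lacks required key {k!r}")
    codes, uniques = pd.factorize(
        pd.MultiIndex.from_frame(meta[keys]), sort=True)
    n_groups = len(uniques)
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_groups, len(codes)))
    sums = np.asarray((ind @ sp.csr_matrix(counts)).todense())
    sizes = np.bincount(codes, minlength=n_groups)
    sample_ids = ["|".join(map(str, tup)) for tup in uniques]
    group_sizes = pd.DataFrame(list(uniques), columns=keys)
    group_sizes["n_cells"] = sizes
    group_sizes.index = sample_ids
    keep = sizes >= min_cells
    counts_df = pd.DataFrame(sums.T[:, keep].astype(np.int64), index=list(genes),
                             columns=[s for s, k in zip(sample_ids, keep) if k])
    sample_meta = group_sizes.loc[keep].copy()
    return PseudobulkSet(counts=counts_df, sample_meta=sample_meta,
                         group_sizes=group_sizes)


def filter_cell_types(group_sizes: pd.DataFrame, min_cells: int = 5,
                      min_replicates: int = 2) -> list:
    """Cell types with >= min_cells cells in >= min_replicates replicates in
    each species, evaluated on pre-drop group sizes (cells pooled across
    individuals within species x replicate)."""
    kept = []
    for ct, sub in group_sizes.groupby("cell_type", sort=True):
        per_rep = (sub.groupby(["species", "replicate"])["n_cells"].sum()
                   .reset_index())
        ok = True
        for spc, s in per_rep.groupby("species"):
            if (s["n_cells"] >= min_cells).sum() < min_replicates:
                ok = False
        if per_rep["species"].nunique() < 2:
            ok = False
        if ok:
            kept.append(ct)
    return kept


def filter_genes_expr(pb: PseudobulkSet, min_count: int = 5) -> list:
    """Expression filter for one cell type's pseudobulk.

    Keep a gene iff its CPM is >= min_count / median(lib size) * 1e6 in at
    least as many samples as the smaller species group has, and its total
    count across samples is >= 15.
    """
    lib = pb.lib_sizes.to_numpy(dtype=float)
    counts = pb.counts.to_numpy(dtype=float)
    n_per_species = pb.sample_meta.groupby("species").size()
    if len(n_per_species) < 2 or (n_per_species < 2).any():
        raise ValueError("need >= 2 samples per species to filter genes")
    n_min = int(n_per_species.min())
    cpm_cut = min_count / np.median(lib) * 1e6
    cpm = counts / lib * 1e6
    keep = ((cpm >= cpm_cut).sum(axis=1) >= n_min) & (counts.sum(axis=1) >= 15)
    return list(pb.counts.index[keep])


def composition_pcs(proportions: pd.DataFrame, m: int = 2):
    """Centered PCA of the sample x cell-type proportion matrix.

    Returns (scores: samples x m DataFrame, variance_explained: length-m
    array). Proportions must sum to 1 per sample.
    """
    x = proportions.to_numpy(dtype=float)
    if x.shape[0] < m:
        raise ValueError(f"need at least {m} samples for {m} components")
    if not np.allclose(x.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("per-sample proportions must sum to 1")
    pca = PCA(n_components=m, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i+1}" for i in range(m)]
    return (pd.DataFrame(scores, index=proportions.index, columns=cols),
            pca.explained_variance_ratio_)


def celltype_proportions(meta: pd.DataFrame) -> pd.DataFrame:
    """Per sample (individual x replicate), the proportion of cells of each
    cell type."""
    tab = pd.crosstab([meta["species"], meta["individual"], meta["replicate"]],
                      meta["cell_type"])
    prop = tab.div(tab.sum(axis=1), axis=0)
    prop.index = ["|".join(map(str, t)) for t in prop.index]
    return prop


def pearson_residuals(counts, theta: float = 100.0, clip: float | None = None):
    """Analytic Pearson residuals of a cell x gene count matrix.

    mu_cg = lib_c * gene_total_g / grand_total; residual = (y - mu) /
    sqrt(mu + mu^2/theta), clipped at sqrt(n_cells) by default. A generic
    stand-in for any variance-stabilised residual matrix.
    """
    y = np.asarray(sp.csr_matrix(counts).todense(), dtype=float)
    lib = y.sum(axis=1, keepdims=True)
    gene = y.sum(axis=0, keepdims=True)
    total = y.sum()
    mu = lib * gene / max(total, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (y - mu) / np.sqrt(mu + mu ** 2 / theta)
    r[~np.isfinite(r)] = 0.0
    c = np.sqrt(y.shape[0]) if clip is None else clip
    return np.clip(r, -c, c)
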