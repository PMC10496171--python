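"""Synthetic two-species single-cell study with planted ground truth.

Generates everything the downstream stages consume, together with the truth
they are later scored against:

* per-gene motif memberships, DE indicators and log2 effects (``beta``,
  chimpanzee minus human);
* diploid cells of both species with negative-binomial UMI counts,
  individual and replicate random effects, and QC metadata;
* tetraploid hybrid cells whose human/chimpanzee allele split encodes a
  planted per-gene cis fraction ``rho`` — the expected allelic log2 ratio
  (chimp over human) is exactly ``rho * beta``;
* a TF -> target promoter-motif network in which driver TFs' targets track
  the TF's DE pattern;
* a PSL alignment fixture with keep/drop truth for the ortho-exon filters.

Every generator is a pure function of (config, seed); seeds are drawn from
named substreams of the config's master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import ConfigError, SimulationConfig
from .orthoexons import AlignmentHit

HUMAN, CHIMP = "human", "chimp"
SPECIES_CODE = {HUMAN: -0.5, CHIMP: +0.5}


@dataclass
class GroundTruth:
    """Planted parameters: what the estimators should recover."""

    genes: list
    celltypes: list
    motif_of_gene: np.ndarray      # (G,) int, z_g
    de_indicator: np.ndarray       # (G, C) {0,1}, delta_gc
    effect: np.ndarray             # (G, C) log2FC beta_gc, chimp minus human
    cis_fraction: np.ndarray       # (G,) rho_g in [0, 1]
    baseline: np.ndarray           # (G,) expected UMI per cell, lambda_g
    indiv_effect: np.ndarray       # (G, n_indiv_total) log2 random intercepts
    rep_effect: np.ndarray         # (G, n_replicates)
    tf_edges: list = field(default_factory=list)  # (tf_gene, target, slope)
    driver_tfs: list = field(default_factory=list)
    tf_genes: list = field(default_factory=list)

    def to_frames(self):
        per_gene = pd.DataFrame({
            "gene": self.genes,
            "motif": self.motif_of_gene,
            "cis_fraction": self.cis_fraction,
            "baseline": self.baseline,
        })
        eff = pd.DataFrame(self.effect, index=self.genes, columns=self.celltypes)
        edges = pd.DataFrame(self.tf_edges, columns=["tf", "target", "slope"])
        return per_gene, eff, edges


@dataclass
class SyntheticStudy:
    """Everything downstream stages consume, plus the planted truth."""

    counts: sp.csr_matrix | None = None          # barcode x gene, diploid
    cell_meta: pd.DataFrame | None = None
    hybrid_human: sp.csr_matrix | None = None    # barcode x gene, human allele
    hybrid_chimp: sp.csr_matrix | None = None
    hybrid_meta: pd.DataFrame | None = None
    promoter_motifs: dict | None = None          # motif_id -> {targets, tfs}
    truth: GroundTruth | None = None
    config: SimulationConfig | None = None


def _nb_draw(rng, mean, dispersion):
    """NB(mean, phi) with var = mu + phi mu^2, via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, dispersion * mean[pos])
        out[pos] = rng.poisson(lam)
    return out


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Draw motif memberships, DE indicators, effects and cis fractions.

    z_g ~ Categorical(motif_weights); delta_gc ~ Bernoulli(q[z_g, c]);
    beta_gc ~ N(0, effect_sd^2) where delta = 1, else 0;
    rho_g ~ Beta(cis_alpha, cis_beta); lambda_g log10-uniform over
    ``baseline_logmean_range``.
    """
    rng = config.rng("truth")
    g, c = config.n_genes, config.n_celltypes
    genes = [f"g{i:05d}" for i in range(g)]
    celltypes = [f"ct{j:02d}" for j in range(config.n_celltypes)]
    z = rng.choice(config.K_motifs, size=g, p=config.motif_weights)
    q = config.motif_matrix[z]  # (G, C)
    delta = (rng.random((g, c)) < q).astype(np.int8)
    beta = np.where(delta == 1, rng.normal(0.0, config.effect_sd, (g, c)), 0.0)
    rho = rng.beta(config.cis_alpha, config.cis_beta, g)
    lo, hi = config.baseline_logmean_range
    lam = 10.0 ** rng.uniform(lo, hi, g)
    n_indiv = 2 * config.n_individuals_per_species
    u = rng.normal(0.0, config.indiv_sd, (g, n_indiv)) if config.indiv_sd > 0 \
        else np.zeros((g, n_indiv))
    v = rng.normal(0.0, config.rep_sd, (g, config.n_replicates)) \
        if config.rep_sd > 0 else np.zeros((g, config.n_replicates))
    return GroundTruth(genes=genes, celltypes=celltypes, motif_of_gene=z,
                       de_indicator=delta, effect=beta, cis_fraction=rho,
                       baseline=lam, indiv_effect=u, rep_effect=v)


def individual_names(config: SimulationConfig):
    nh = config.n_individuals_per_species
    return ([f"H{i+1}" for i in range(nh)], [f"C{i+1}" for i in range(nh)])


def simulate_species_cells(truth: GroundTruth, config: SimulationConfig) -> SyntheticStudy:
    """Diploid cells: count_g ~ NB(lambda_g * 2^(s*beta + u_i + v_r), phi).

    Species coding s = -1/2 (human) / +1/2 (chimpanzee), so beta is the full
    chimp-vs-human log2 fold change. Barcode metadata (genome read counts,
    mitochondrial fraction, genes detected) is drawn to pass the default QC
    unless ``inject_qc_failures`` is set, in which case ~3% of cells get a
    failing value and a truth flag.
    """
    rng = config.rng("species")
    meta_rng = config.rng("meta")
    lam = truth.baseline
    humans, chimps = individual_names(config)
    indiv_all = humans + chimps
    blocks, metas = [], []
    for sp_name, indivs in ((HUMAN, humans), (CHIMP, chimps)):
        s = SPECIES_CODE[sp_name]
        for indiv in indivs:
            i_idx = indiv_all.index(indiv)
            for r in range(config.n_replicates):
                rep = f"rep{r+1}"
                for c_idx, ct in enumerate(truth.celltypes):
                    n = config.n_cells_per_sample
                    mu = lam * 2.0 ** (s * truth.effect[:, c_idx]
                                       + truth.indiv_effect[:, i_idx]
                                       + truth.rep_effect[:, r])
                    counts = _nb_draw(rng, np.broadcast_to(mu, (n, lam.size)),
                                      config.nb_dispersion)
                    blocks.append(sp.csr_matrix(counts))
                    total_reads = meta_rng.integers(20_000, 60_000, n)
                    own_frac = meta_rng.uniform(0.95, 0.995, n)
                    own = (total_reads * own_frac).astype(int)
                    other = total_reads - own
                    metas.append(pd.DataFrame({
                        "species": sp_name, "individual": indiv,
                        "replicate": rep, "cell_type": ct,
                        "reads_genomeA": own if sp_name == HUMAN else other,
                        "reads_genomeB": other if sp_name == HUMAN else own,
                        "mito_fraction": meta_rng.uniform(0.005, 0.15, n),
                        "genes_detected": meta_rng.integers(2500, 6000, n),
                        "qc_fail_truth": False,
                    }))
    counts = sp.vstack(blocks).tocsr()
    meta = pd.concat(metas, ignore_index=True)
    meta.insert(0, "barcode", [f"cell{i:06d}" for i in range(len(meta))])
    if config.inject_qc_failures:
        fail = meta_rng.random(len(meta)) < 0.03
        mode = meta_rng.integers(0, 3, len(meta))
        meta.loc[fail & (mode == 0), "genes_detected"] = 500
        meta.loc[fail & (mode == 1), "mito_fraction"] = 0.35
        meta.loc[fail & (mode == 2), "mito_fraction"] = 0.0002
        meta.loc[fail, "qc_fail_truth"] = True
    return SyntheticStudy(counts=counts, cell_meta=meta, truth=truth,
                          config=config)


def hybrid_allele_probability(rho, beta):
    """Human-allele success probability p = 1 / (1 + 2^(rho*beta)).

    Chosen so the expected allelic log2 ratio (chimp/human) equals
    rho * beta, the quantity the cis-proportion estimator assumes.
    """
    return 1.0 / (1.0 + 2.0 ** (np.asarray(rho) * np.asarray(beta)))


def simulate_hybrid_cells(truth: GroundTruth, config: SimulationConfig,
                          n_cells_per_sample: int | None = None) -> SyntheticStudy:
    """Tetraploid hybrid cells: total ~ NB, human allele ~ Binomial(total, p).

    One sample = replicate x cell type. The trans environment is shared by
    the two alleles within a cell, so the allele split isolates the cis
    effect; replicate random effects enter only through the totals.
    """
    rng = config.rng("hybrid")
    n = n_cells_per_sample or config.n_cells_per_sample
    lam = truth.baseline
    blocks_h, blocks_c, metas = [], [], []
    for r in range(config.n_replicates):
        rep = f"rep{r+1}"
        for c_idx, ct in enumerate(truth.celltypes):
            mu = lam * 2.0 ** truth.rep_effect[:, r]
            total = _nb_draw(rng, np.broadcast_to(mu, (n, lam.size)),
                             config.nb_dispersion)
            p = hybrid_allele_probability(truth.cis_fraction,
                                          truth.effect[:, c_idx])
            human = rng.binomial(total, np.broadcast_to(p, total.shape))
            blocks_h.append(sp.csr_matrix(human))
            blocks_c.append(sp.csr_matrix(total - human))
            metas.append(pd.DataFrame({
                "replicate": rep, "cell_type": ct,
                "mito_fraction": rng.uniform(0.005, 0.15, n),
                "genes_detected": rng.integers(3000, 7000, n),
            }))
    meta = pd.concat(metas, ignore_index=True)
    meta.insert(0, "barcode", [f"hyb{i:06d}" for i in range(len(meta))])
    return SyntheticStudy(hybrid_human=sp.vstack(blocks_h).tocsr(),
                          hybrid_chimp=sp.vstack(blocks_c).tocsr(),
                          hybrid_meta=meta, truth=truth, config=config)


def simulate_tf_network(truth: GroundTruth, config: SimulationConfig):
    """Plant a TF -> target network; returns (promoter_motifs, truth).

    Driver TFs receive a DE pattern across all cell types; each driver's
    targets get beta = driver_slope * (TF pattern) + N(0, driver_noise_sd^2)
    and a small cis fraction (the divergence is trans-driven). Non-driver
    TFs get motifs whose targets keep their independent base-truth effects.
    TF genes' baselines are floored at 0.5 UMI/cell: a driver must itself be
    expressed to be discoverable.
    """
    if config.n_tfs == 0:
        return {}, truth
    rng = config.rng("tf")
    g = config.n_genes
    n_needed = config.n_tfs * (1 + config.targets_per_tf)
    if n_needed > g:
        raise ConfigError("targets_per_tf * n_tfs exceeds available genes")
    chosen = rng.choice(g, size=n_needed, replace=False)
    tf_idx = chosen[:config.n_tfs]
    target_pool = chosen[config.n_tfs:]
    promoter_motifs = {}
    tf_genes = [truth.genes[i] for i in tf_idx]
    driver_tfs = tf_genes[:config.n_driver_tfs]
    c = config.n_celltypes
    for t, tf_i in enumerate(tf_idx):
        tf_gene = truth.genes[tf_i]
        targets = target_pool[t * config.targets_per_tf:
                              (t + 1) * config.targets_per_tf]
        target_genes = [truth.genes[i] for i in targets]
        motif_id = f"M_{tf_gene}"
        promoter_motifs[motif_id] = {"targets": set(target_genes),
                                     "tfs": {tf_gene}}
        truth.baseline[tf_i] = max(truth.baseline[tf_i], 0.5)
        is_driver = t < config.n_driver_tfs
        if is_driver:
            pattern = rng.normal(0.0, config.effect_sd, c)
            truth.effect[tf_i] = pattern
            truth.de_indicator[tf_i] = 1
            for j in targets:
                noise = (rng.normal(0.0, config.driver_noise_sd, c)
                         if config.driver_noise_sd > 0 else 0.0)
                truth.effect[j] = config.driver_slope * pattern + noise
                truth.de_indicator[j] = 1
                truth.cis_fraction[j] = rng.beta(1.0, 9.0)
                truth.baseline[j] = max(truth.baseline[j], 0.5)
                truth.tf_edges.append((tf_gene, truth.genes[j],
                                       config.driver_slope))
        else:
            for j in targets:
                truth.tf_edges.append((tf_gene, truth.genes[j], 0.0))
    truth.driver_tfs = driver_tfs
    truth.tf_genes = tf_genes
    return promoter_motifs, truth


def simulate_embedding(cell_meta: pd.DataFrame, config: SimulationConfig,
                       dim: int = 10, separation: float = 10.0):
    """Gaussian cluster embedding: one unit-variance blob per true cell type.

    Returns (centroids: label -> vector, coords: barcode x dim DataFrame).
    Stands in for a batch-corrected reference PC space.
    """
    rng = config.rng("embedding")
    labels = sorted(cell_meta["cell_type"].unique())
    centroids = {}
    for j, lab in enumerate(labels):
        v = np.zeros(dim)
        v[j % dim] = separation * (1 + j // dim)
        centroids[lab] = v
    coords = np.vstack([centroids[lab] for lab in cell_meta["cell_type"]])
    coords = coords + rng.normal(0.0, 1.0, coords.shape)
    return centroids, pd.DataFrame(coords, index=cell_meta["barcode"].values)


# --------------------------------------------------------------------------
# PSL fixture
# --------------------------------------------------------------------------

EXON_LEN = 200
_SCENARIOS = [
    "clean", "low_identity", "identity_at_threshold", "indel_drop",
    "indel_keep", "multimap_resolved", "multimap_tie", "recip_human_fail",
    "recip_chimp_fail", "no_back_map", "overlap_one_base", "minus_strand",
]


@dataclass
class PslFixture:
    forward: list
    back_to_human: list
    chimp_self: list
    truth: pd.DataFrame  # exon_id, gene_id, keep, reason, scenario


def _mk_hit(exon, gene, src, tgt_chrom, tgt_start, matches, qgap=0, tgap=0,
            strand="+"):
    return AlignmentHit(
        query_exon_id=exon, query_gene_id=gene, query_length=EXON_LEN,
        matches=matches, mismatches=EXON_LEN - matches - qgap,
        query_gap_bases=qgap, target_gap_bases=tgap,
        target_chrom=tgt_chrom, target_start=tgt_start,
        target_end=tgt_start + EXON_LEN, strand=strand, source_locus=src)


def simulate_psl_fixture(n_exons: int, seed: int) -> PslFixture:
    """Alignment-hit fixture spanning every filter decision boundary.

    Genes of five colinear exons cycle through twelve scenarios (identity at
    0.79/0.80, indels at 0.20/0.21, multimap resolution and ties, reciprocal
    failures, one-base overlaps, minus strand). Keep/drop truth follows from
    each scenario's construction, independently of the filter code.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    rng = np.random.default_rng(seed)
    forward, back_h, back_c, rows = [], [], [], []
    exons_per_gene = 5
    n_genes = -(-n_exons // exons_per_gene)
    emitted = 0
    for gi in range(n_genes):
        scenario = _SCENARIOS[gi % len(_SCENARIOS)]
        gene = f"gene{gi:04d}"
        h_chrom = f"hchr{gi % 4 + 1}"
        c_chrom = f"cchr{gi % 4 + 1}"
        base_h = 1_000_000 + gi * 300_000
        base_c = 2_000_000 + gi * 300_000
        for e in range(exons_per_gene):
            if emitted >= n_exons:
                break
            emitted += 1
            exon = f"{gene}_e{e}"
            src = (h_chrom, base_h + e * 1000, base_h + e * 1000 + EXON_LEN)
            tgt = base_c + e * 1000
            keep, reason = True, ""
            if scenario == "clean":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 190))
            elif scenario == "low_identity":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 158))
                keep, reason = False, "low_identity"
            elif scenario == "identity_at_threshold":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 160))
            elif scenario == "indel_drop":  # gaps 42/200 = 0.21 > 0.20
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 160,
                                       qgap=22, tgap=20))
                keep, reason = False, "indel"
            elif scenario == "indel_keep":  # gaps 40/200 = 0.20, not greater
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 160,
                                       qgap=20, tgap=20))
            elif scenario == "multimap_resolved":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 190))
                # decoy: isolated loci > 100 kb apart, zero neighbor support
                forward.append(_mk_hit(exon, gene, src, "cchr_decoy",
                                       50_000_000 + gi * 10_000_000
                                       + e * 500_000, 180))
            elif scenario == "multimap_tie":
                # two colinear clusters -> equal neighbor counts; higher
                # identity (184 vs 170) wins the tie
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 184))
                forward.append(_mk_hit(exon, gene, src, "cchr_alt",
                                       9_000_000 + gi * 300_000 + e * 1000,
                                       170))
            elif scenario == "recip_human_fail":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 190))
                keep, reason = False, "reciprocal-human"
            elif scenario == "recip_chimp_fail":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 190))
                keep, reason = False, "reciprocal-chimp"
            elif scenario == "no_back_map":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 190))
                keep, reason = False, "no-reciprocal-hit"
            elif scenario == "overlap_one_base":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 190))
            elif scenario == "minus_strand":
                forward.append(_mk_hit(exon, gene, src, c_chrom, tgt, 190,
                                       strand="-"))
            # reciprocal records for scenarios that reach that stage
            if scenario not in ("low_identity", "indel_drop", "no_back_map"):
                chosen_chrom, chosen_tgt = c_chrom, tgt
                if scenario == "recip_human_fail":
                    back_h.append(_mk_hit(exon, gene, src, "hchr_wrong",
                                          src[1], 190))
                elif scenario == "overlap_one_base":
                    back_h.append(_mk_hit(exon, gene, src, h_chrom,
                                          src[2] - 1, 190))
                else:
                    back_h.append(_mk_hit(exon, gene, src, h_chrom, src[1],
                                          190))
                if scenario == "recip_chimp_fail":
                    back_c.append(_mk_hit(exon, gene, src, chosen_chrom,
                                          chosen_tgt + 10_000, 190))
                else:
                    back_c.append(_mk_hit(exon, gene, src, chosen_chrom,
                                          chosen_tgt, 190))
            rows.append(dict(exon_id=exon, gene_id=gene, keep=keep,
                             reason=reason, scenario=scenario,
                             expected_chrom=c_chrom if keep else "",
                             expected_start=tgt if keep else -1))
    for lst in (forward, back_h, back_c):
        rng.shuffle(lst)
    return PslFixture(forward=forward, back_to_human=back_h,
                      chimp_self=back_c,
                      truth=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# disk round trip
# --------------------------------------------------------------------------

def write_study(study: SyntheticStudy, out_dir) -> None:
    """Persist a study as MTX triplets + TSV metadata + truth tables."""
    from pathlib import Path

    from . import io as _io

    out = Path(out_dir)
    truth = study.truth
    if study.counts is not None:
        _io.write_mtx(out / "diploid", study.counts,
                      study.cell_meta["barcode"], truth.genes)
        _io.write_tsv(out / "diploid" / "cell_meta.tsv", study.cell_meta)
    if study.hybrid_human is not None:
        _io.write_mtx(out / "hybrid_human", study.hybrid_human,
                      study.hybrid_meta["barcode"], truth.genes)
        _io.write_mtx(out / "hybrid_chimp", study.hybrid_chimp,
                      study.hybrid_meta["barcode"], truth.genes)
        _io.write_tsv(out / "hybrid_meta.tsv", study.hybrid_meta)
    if truth is not None:
        per_gene, eff, edges = truth.to_frames()
        _io.write_tsv(out / "truth_genes.tsv", per_gene)
        _io.write_tsv(out / "truth_effects.tsv", eff.reset_index(names="gene"))
        _io.write_tsv(out / "truth_tf_edges.tsv", edges)
    if study.promoter_motifs:
        rows = [{"motif_id": m, "target_gene": t, "tf_gene": tf}
                for m, d in sorted(study.promoter_motifs.items())
                for t in sorted(d["targets"]) for tf in sorted(d["tfs"])]
        _io.write_tsv(out / "promoter_motifs.tsv", pd.DataFrame(rows))
    if study.config is not None:
        study.config.to_yaml(out / "config.yaml")
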