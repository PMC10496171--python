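"""End-to-end orchestration: simulate -> preprocess -> de -> cormotif ->
cistrans -> tfdrivers, with a manifest, per-stage caching and structured
logs.

Stages exchange data through the run directory (MTX triplets and TSVs), so
a rerun can resume from any stage whose recorded input hashes still match.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cistrans as _ct
from . import cormotif as _cm
from . import de as _de
from . import io as _io
from . import preprocess as _pp
from . import simulate as _sim
from . import tfdrivers as _tf
from .config import PipelineConfig

log = logging.getLogger("ebcomp")

STAGE_ORDER = ("simulate", "preprocess", "de", "cormotif", "cistrans",
               "tfdrivers")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


class RunManifest:
    """Per-stage record of inputs, parameters, outputs and timing."""

    def __init__(self, path: Path):
        self.path = Path(path)
        self.data = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def stage_fresh(self, stage, input_hashes, params) -> bool:
        entry = self.data.get(stage)
        if not entry:
            return False
        if entry["inputs"] != input_hashes or entry["params"] != params:
            return False
        return all(Path(p).exists() for p in entry["outputs"])

    def record(self, stage, input_hashes, params, outputs, seconds, seed):
        self.data[stage] = {
            "inputs": input_hashes,
            "params": params,
            "outputs": [str(p) for p in outputs],
            "wall_clock_s": round(seconds, 3),
            "seed_stream": seed,
        }
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _params_of(cfg: PipelineConfig, keys) -> dict:
    d = cfg.to_dict()
    return {k: d[k] for k in keys}


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, run: Path) -> list:
    sim = cfg.simulation
    truth = _sim.simulate_truth(sim)
    promoter_motifs, truth = _sim.simulate_tf_network(truth, sim)
    study = _sim.simulate_species_cells(truth, sim)
    hyb = _sim.simulate_hybrid_cells(truth, sim)
    study.hybrid_human, study.hybrid_chimp = hyb.hybrid_human, hyb.hybrid_chimp
    study.hybrid_meta = hyb.hybrid_meta
    study.promoter_motifs = promoter_motifs
    out = run / "sim"
    _sim.write_study(study, out)
    centroids, coords = _sim.simulate_embedding(study.cell_meta, sim)
    cents = pd.DataFrame(centroids).T
    cents.insert(0, "label", cents.index)
    _io.write_tsv(out / "centroids.tsv", cents.reset_index(drop=True))
    coords.reset_index(names="barcode").to_csv(out / "cell_coords.tsv",
                                               sep="\t", index=False)
    return [out]


def stage_preprocess(cfg: PipelineConfig, run: Path) -> list:
    sim_dir = run / "sim"
    counts, barcodes, genes = _io.read_mtx(sim_dir / "diploid")
    meta = _io.read_tsv(sim_dir / "diploid" / "cell_meta.tsv")
    meta["assigned_species"] = _pp.assign_species(
        meta["reads_genomeA"], meta["reads_genomeB"], cfg.species_purity)
    keep = _pp.qc_filter_cells(meta, cfg.min_genes_detected, cfg.mito_low,
                               cfg.mito_high)
    keep &= meta["assigned_species"].isin([_pp.SPECIES_A, _pp.SPECIES_B])
    cents = _io.read_tsv(sim_dir / "centroids.tsv")
    centroids = {row["label"]: row.drop("label").to_numpy(dtype=float)
                 for _, row in cents.iterrows()}
    coords = pd.read_csv(sim_dir / "cell_coords.tsv", sep="\t",
                         index_col="barcode")
    labels = _pp.assign_labels(centroids, coords)
    meta = meta.loc[keep.to_numpy()].copy()
    meta["species"] = meta["assigned_species"].map(
        {_pp.SPECIES_A: "human", _pp.SPECIES_B: "chimp"})
    meta["cell_type"] = labels.loc[meta["barcode"]].to_numpy()
    counts = counts[keep.to_numpy()]
    pb = _pp.make_pseudobulk(counts, meta, genes,
                             min_cells=cfg.min_cells_per_sample)
    kept_cts = _pp.filter_cell_types(pb.group_sizes, cfg.min_cells_celltype,
                                     cfg.min_replicates_celltype)
    keep_cols = pb.sample_meta["cell_type"].isin(kept_cts)
    pb_counts = pb.counts.loc[:, keep_cols.values]
    out = run / "pseudobulk"
    _io.write_mtx(out, pb_counts.T.to_numpy(), pb_counts.columns,
                  pb_counts.index)
    _io.write_tsv(out / "sample_meta.tsv",
                  pb.sample_meta.loc[keep_cols].reset_index(names="sample"))
    _io.write_tsv(out / "group_sizes.tsv",
                  pb.group_sizes.reset_index(names="sample"))
    _io.write_tsv(out / "labels.tsv", meta[["barcode", "cell_type"]])
    return [out]


def _load_pseudobulk(run: Path) -> _pp.PseudobulkSet:
    mat, samples, genes = _io.read_mtx(run / "pseudobulk")
    counts = pd.DataFrame(np.asarray(mat.todense()).T, index=genes,
                          columns=samples)
    sample_meta = _io.read_tsv(run / "pseudobulk" / "sample_meta.tsv")
    sample_meta = sample_meta.set_index("sample").loc[samples]
    group_sizes = _io.read_tsv(run / "pseudobulk" / "group_sizes.tsv")
    return _pp.PseudobulkSet(counts=counts, sample_meta=sample_meta,
                             group_sizes=group_sizes.set_index("sample"))


def stage_de(cfg: PipelineConfig, run: Path) -> list:
    pb = _load_pseudobulk(run)
    out = run / "de"
    out.mkdir(parents=True, exist_ok=True)
    covs = None
    if cfg.composition_pcs > 0:
        labels = _io.read_tsv(run / "pseudobulk" / "labels.tsv")
        meta = _io.read_tsv(run / "sim" / "diploid" / "cell_meta.tsv")
        merged = meta.merge(labels, on="barcode", suffixes=("_true", ""))
        merged["species"] = pd.Series(_pp.assign_species(
            merged["reads_genomeA"], merged["reads_genomeB"]),
            index=merged.index).map({_pp.SPECIES_A: "human",
                                     _pp.SPECIES_B: "chimp"})
        props = _pp.celltype_proportions(merged)
        covs, _ = _pp.composition_pcs(props, cfg.composition_pcs)
    frames = []
    for ct in sorted(pb.sample_meta["cell_type"].unique()):
        sub = pb.subset_celltype(ct)
        n_sp = sub.sample_meta.groupby("species").size()
        if len(n_sp) < 2 or (n_sp < 2).any():
            log.warning("de: skipping %s (needs >= 2 samples per species)", ct)
            continue
        cov_ct = None
        if covs is not None:
            key = (sub.sample_meta["species"].astype(str) + "|"
                   + sub.sample_meta["individual"].astype(str) + "|"
                   + sub.sample_meta["replicate"].astype(str))
            try:
                cov_ct = covs.loc[key].to_numpy()
            except KeyError:
                cov_ct = None
        try:
            fit = _de.de_for_celltype(sub, min_count=cfg.min_count,
                                      covariates=cov_ct)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("de: skipping %s (%s)", ct, exc)
            continue
        fit.insert(0, "cell_type", ct)
        frames.append(fit)
        _io.write_tsv(out / f"de_{ct}.tsv",
                      fit[["cell_type", "gene", "log2fc", "se", "t", "df",
                           "p", "fdr"]])
    if not frames:
        raise StageError("de", "no-celltypes", "no cell type could be fitted")
    _io.write_tsv(out / "de_all.tsv", pd.concat(frames, ignore_index=True))
    return [out]


def _species_umi(pb: _pp.PseudobulkSet) -> dict:
    out = {}
    for spc, sub in pb.sample_meta.groupby("species"):
        cols = sub.index
        umi = (pb.counts[cols].T.groupby(sub["cell_type"].values).sum().T)
        out[spc] = umi
    return out


def stage_cormotif(cfg: PipelineConfig, run: Path) -> list:
    pb = _load_pseudobulk(run)
    tstats = _cm.condition_tstats(pb, min_count=cfg.min_count)
    k_lo, k_hi = cfg.k_range
    model = _cm.select_k_bic(tstats, range(k_lo, k_hi + 1),
                             n_starts=cfg.n_starts, tol=cfg.em_tol,
                             max_iter=cfg.em_max_iter, seed=cfg.seed)
    out = run / "cormotif"
    out.mkdir(parents=True, exist_ok=True)
    (out / "model.json").write_text(json.dumps({
        "K": model.K, "Q": model.Q.tolist(), "pi": model.pi.tolist(),
        "loglik": model.loglik, "bic": model.bic,
        "bic_by_k": {str(k): v for k, v in model.bic_by_k.items()},
        "celltypes": model.celltypes,
    }, indent=2))
    _io.write_tsv(out / "de_posteriors.tsv",
                  model.de_post.reset_index(names="gene"))
    _io.write_tsv(out / "motif_membership.tsv",
                  model.gene_motif_post.reset_index(names="gene"))
    calls, n_de = _cm.classify_de(model, cfg.de_posterior)
    _io.write_tsv(out / "de_calls.tsv", calls.reset_index(names="gene"))
    de_all = _io.read_tsv(run / "de" / "de_all.tsv")
    de_fits = {ct: sub for ct, sub in de_all.groupby("cell_type")}
    umi = _species_umi(pb)
    n_ct = model.de_post.shape[1]
    conserved = _cm.classify_conserved(
        model, umi, de_fits, threshold=cfg.de_posterior,
        min_celltypes=min(10, n_ct))
    _io.write_tsv(out / "conserved_genes.tsv", pd.DataFrame({
        "gene": conserved.conserved}))
    restricted = _cm.find_restricted_de(model, umi, hi=cfg.de_posterior,
                                        lo=1 - cfg.de_posterior)
    _io.write_tsv(out / "restricted_de.tsv", restricted)
    return [out]


def stage_cistrans(cfg: PipelineConfig, run: Path) -> list:
    sim_dir = run / "sim"
    hh, hb, genes = _io.read_mtx(sim_dir / "hybrid_human")
    hc, _, _ = _io.read_mtx(sim_dir / "hybrid_chimp")
    hmeta = _io.read_tsv(sim_dir / "hybrid_meta.tsv")
    keep = _pp.qc_filter_cells(hmeta, cfg.min_genes_detected_hybrid,
                               cfg.mito_low, cfg.mito_high)
    hh, hc = hh[keep.to_numpy()], hc[keep.to_numpy()]
    hmeta = hmeta.loc[keep.to_numpy()].reset_index(drop=True)
    de_all = _io.read_tsv(run / "de" / "de_all.tsv")
    dip_fc = de_all.pivot(index="gene", columns="cell_type", values="log2fc")
    dip_se = de_all.pivot(index="gene", columns="cell_type", values="se")
    out = run / "cistrans"
    out.mkdir(parents=True, exist_ok=True)
    hyb_cols, wilcox = {}, []
    for ct in sorted(set(hmeta["cell_type"]) & set(dip_fc.columns)):
        hyb_cols[ct] = _ct.hybrid_logfc(hh, hc, hmeta, ct, genes=genes)
        wt = _ct.hybrid_paired_wilcoxon(hh, hc, hmeta, ct, genes=genes)
        wt.insert(0, "cell_type", ct)
        wilcox.append(wt)
    if not hyb_cols:
        raise StageError("cistrans", "no-celltypes",
                         "no shared cell types between hybrid and diploid DE")
    hyb_fc = pd.DataFrame(hyb_cols)
    est = _ct.build_estimates(hyb_fc, dip_fc, dip_se)
    calls = _io.read_tsv(run / "cormotif" / "de_calls.tsv").set_index("gene")
    classes = _ct.classify_cis_trans(est, calls, cfg.cis_hi, cfg.cis_lo)
    n_sub = min(cfg.lowest_se_n, est.dropna(
        subset=["cis_proportion", "diploid_se"]).shape[0])
    subset, sub_mean, all_mean = _ct.lowest_se_subset(est, n=n_sub)
    _io.write_tsv(out / "estimates.tsv", est)
    _io.write_tsv(out / "classes.tsv", classes)
    _io.write_tsv(out / "hybrid_wilcoxon.tsv",
                  pd.concat(wilcox, ignore_index=True))
    (out / "summary.json").write_text(json.dumps({
        "mean_cis_proportion": all_mean,
        "lowest_se_mean_cis_proportion": sub_mean,
        "lowest_se_n": n_sub}, indent=2))
    return [out]


def stage_tfdrivers(cfg: PipelineConfig, run: Path) -> list:
    est = _io.read_tsv(run / "cistrans" / "estimates.tsv")
    calls = _io.read_tsv(run / "cormotif" / "de_calls.tsv").set_index("gene")
    annotations = _tf.load_motif_annotations(run / "sim" / "promoter_motifs.tsv")
    de_all = _io.read_tsv(run / "de" / "de_all.tsv")
    logfc = de_all.pivot(index="gene", columns="cell_type", values="log2fc")
    universe = logfc.index
    trans_set = _tf.define_trans_de_set(est, calls, cfg.trans_cut)
    enrich = _tf.motif_enrichment(trans_set, annotations, universe)
    enriched = (list(enrich.loc[enrich["fdr"] <= cfg.enrich_fdr, "motif_id"])
                if len(enrich) else [])
    n_de = calls.sum(axis=1)
    expressed = logfc.notna().sum(axis=1)
    candidates = _tf.filter_candidate_tfs(enriched, annotations, n_de,
                                          expressed)
    drivers = _tf.driver_scan(candidates, annotations, logfc, n_de,
                              target_fdr=cfg.driver_fdr)
    out = run / "tfdrivers"
    out.mkdir(parents=True, exist_ok=True)
    _io.write_tsv(out / "motif_enrichment.tsv", enrich)
    _io.write_tsv(out / "drivers.tsv", drivers)
    pd.DataFrame({"gene": trans_set}).to_csv(out / "trans_de_genes.tsv",
                                             sep="\t", index=False)
    return [out]


_STAGE_FUNCS = {
    "simulate": (stage_simulate, [], ["simulation", "seed"]),
    "preprocess": (stage_preprocess, ["sim"],
                   ["min_genes_detected", "mito_low", "mito_high",
                    "species_purity", "min_cells_per_sample",
                    "min_cells_celltype", "min_replicates_celltype"]),
    "de": (stage_de, ["pseudobulk"], ["min_count", "composition_pcs"]),
    "cormotif": (stage_cormotif, ["pseudobulk", "de"],
                 ["min_count", "k_range", "n_starts", "em_tol", "em_max_iter",
                  "de_posterior", "seed"]),
    "cistrans": (stage_cistrans, ["sim", "de", "cormotif"],
                 ["min_genes_detected_hybrid", "cis_hi", "cis_lo",
                  "lowest_se_n", "de_posterior"]),
    "tfdrivers": (stage_tfdrivers, ["sim", "cormotif", "cistrans", "de"],
                  ["trans_cut", "enrich_fdr", "driver_fdr"]),
}


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> RunManifest:
    """Execute the configured stages in dependency order.

    A stage is skipped when the manifest records the same input hashes and
    parameters and its outputs exist; any stage error aborts the run with
    the stage name and a machine-readable code.
    """
    run = Path(cfg.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(run / "MANIFEST.json")
    cfg.to_yaml(run / "config.yaml")
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        func, input_dirs, param_keys = _STAGE_FUNCS[stage]
        input_hashes = {}
        for d in input_dirs:
            p = run / d
            if not p.exists():
                raise StageError(stage, "missing-input",
                                 f"required input {p} not found")
            input_hashes[d] = _io.sha256_tree(p)
        params = json.loads(json.dumps(_params_of(cfg, param_keys)))
        if not force and manifest.stage_fresh(stage, input_hashes, params):
            log.info("%s: cached, skipping", stage)
            continue
        log.info("%s: running", stage)
        t0 = time.time()
        try:
            outputs = func(cfg, run)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(stage, type(exc).__name__, str(exc)) from exc
        manifest.record(stage, input_hashes, params, outputs,
                        time.time() - t0, cfg.seed)
    return manifest
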