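"""The synthetic-study generator: planted truth, distributional behaviour,
determinism, and the alignment-hit fixture."""

import numpy as np
import pytest
import scipy.sparse as sp

from ebcomp.config import ConfigError, SimulationConfig
from ebcomp import io as eio
from ebcomp import simulate as sim


def _cfg(**kw):
    base = dict(n_genes=200, n_celltypes=3, n_cells_per_sample=20, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateTruth:
    def test_zero_motif_matrix_means_no_de(self):
        cfg = _cfg(K_motifs=1, motif_matrix=np.zeros((1, 3)),
                   motif_weights=np.array([1.0]))
        truth = sim.simulate_truth(cfg)
        assert truth.de_indicator.sum() == 0
        assert np.all(truth.effect == 0.0)

    def test_all_ones_motif_montecarlo(self):
        cfg = _cfg(n_genes=10_000, K_motifs=1,
                   motif_matrix=np.ones((1, 3)),
                   motif_weights=np.array([1.0]), effect_sd=1.0)
        truth = sim.simulate_truth(cfg)
        assert truth.de_indicator.mean() == 1.0
        assert abs(truth.effect.std() - 1.0) < 0.03

    def test_determinism(self):
        a = sim.simulate_truth(_cfg())
        b = sim.simulate_truth(_cfg())
        np.testing.assert_array_equal(a.effect, b.effect)
        np.testing.assert_array_equal(a.motif_of_gene, b.motif_of_gene)
        np.testing.assert_array_equal(a.cis_fraction, b.cis_fraction)

    def test_effect_zero_where_not_de(self):
        truth = sim.simulate_truth(_cfg(n_genes=2000))
        assert np.all(truth.effect[truth.de_indicator == 0] == 0.0)

    @pytest.mark.parametrize("field,value", [
        ("n_genes", 0), ("n_celltypes", 0), ("nb_dispersion", -1.0),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            _cfg(**{field: value})

    def test_bad_motif_weights_rejected(self):
        with pytest.raises(ConfigError, match="motif_weights"):
            _cfg(K_motifs=2, motif_matrix=np.zeros((2, 3)),
                 motif_weights=np.array([0.6, 0.6]))


class TestSpeciesCells:
    def test_null_species_balance(self):
        # no effects, no random effects: pseudobulk species means agree
        # within NB sampling error (expected totals ~1e4 per species put the
        # CLT sd of the log2 ratio near 0.03)
        cfg = _cfg(n_genes=60, K_motifs=1, motif_matrix=np.zeros((1, 3)),
                   motif_weights=np.array([1.0]), indiv_sd=0.0, rep_sd=0.0,
                   nb_dispersion=0.05, n_cells_per_sample=80,
                   baseline_logmean_range=(1.0, 1.3))
        truth = sim.simulate_truth(cfg)
        study = sim.simulate_species_cells(truth, cfg)
        counts = np.asarray(study.counts.todense())
        human = counts[(study.cell_meta["species"] == "human").to_numpy()]
        chimp = counts[(study.cell_meta["species"] == "chimp").to_numpy()]
        assert np.all(truth.baseline * human.shape[0] >= 1000)
        ratio = np.log2(chimp.sum(0) / human.sum(0))
        assert np.all(np.abs(ratio) < 0.1)

    def test_zero_baseline_gene_all_zero(self):
        cfg = _cfg(n_genes=50)
        truth = sim.simulate_truth(cfg)
        truth.baseline[7] = 0.0
        study = sim.simulate_species_cells(truth, cfg)
        assert study.counts[:, 7].sum() == 0

    def test_planted_effect_recovered_in_raw_ratio(self):
        cfg = _cfg(n_genes=60, K_motifs=1, motif_matrix=np.ones((1, 3)),
                   motif_weights=np.array([1.0]), indiv_sd=0.0, rep_sd=0.0,
                   n_cells_per_sample=60, baseline_logmean_range=(0.7, 1.0))
        truth = sim.simulate_truth(cfg)
        truth.effect[:] = 1.0
        study = sim.simulate_species_cells(truth, cfg)
        counts = np.asarray(study.counts.todense())
        human = counts[(study.cell_meta["species"] == "human").to_numpy()]
        chimp = counts[(study.cell_meta["species"] == "chimp").to_numpy()]
        ratio = np.log2(chimp.sum(0) / human.sum(0))
        assert abs(ratio.mean() - 1.0) < 0.1

    def test_metadata_passes_default_qc(self, small_study):
        meta = small_study.cell_meta
        assert (meta["genes_detected"] >= 1000).all()
        assert meta["mito_fraction"].between(0.001, 0.2).all()

    def test_qc_failures_injected_only_on_flag(self):
        cfg = _cfg(inject_qc_failures=True)
        truth = sim.simulate_truth(cfg)
        study = sim.simulate_species_cells(truth, cfg)
        assert study.cell_meta["qc_fail_truth"].any()


class TestHybridCells:
    @pytest.mark.parametrize("rho,beta,expected", [
        (0.0, 2.5, 0.5),       # no cis effect -> balanced alleles
        (1.0, 1.0, 1.0 / 3.0),
        (1.0, -1.0, 2.0 / 3.0),
    ])
    def test_allele_probability(self, rho, beta, expected):
        assert sim.hybrid_allele_probability(rho, beta) == pytest.approx(
            expected, abs=1e-12)

    def test_counts_nonnegative_and_deterministic(self, small_truth,
                                                  small_config):
        a = sim.simulate_hybrid_cells(small_truth, small_config)
        b = sim.simulate_hybrid_cells(small_truth, small_config)
        assert (a.hybrid_human.data >= 0).all()
        assert (a.hybrid_chimp.data >= 0).all()
        assert (a.hybrid_human != b.hybrid_human).nnz == 0
        assert (a.hybrid_chimp != b.hybrid_chimp).nnz == 0

    def test_allelic_ratio_encodes_rho_beta(self):
        cfg = _cfg(n_genes=40, n_celltypes=1, K_motifs=1,
                   motif_matrix=np.ones((1, 1)),
                   motif_weights=np.array([1.0]), rep_sd=0.0,
                   n_cells_per_sample=400,
                   baseline_logmean_range=(1.0, 1.3))
        truth = sim.simulate_truth(cfg)
        truth.effect[:] = 1.0
        truth.cis_fraction[:] = 1.0
        hyb = sim.simulate_hybrid_cells(truth, cfg)
        h = np.asarray(hyb.hybrid_human.sum(axis=0)).ravel()
        c = np.asarray(hyb.hybrid_chimp.sum(axis=0)).ravel()
        assert abs(np.log2(c / h).mean() - 1.0) < 0.1


class TestTfNetwork:
    def _net(self, **kw):
        base = dict(n_genes=600, n_celltypes=20, n_tfs=6, n_driver_tfs=3,
                    targets_per_tf=10, seed=5)
        base.update(kw)
        cfg = SimulationConfig(**base)
        truth = sim.simulate_truth(cfg)
        return sim.simulate_tf_network(truth, cfg), cfg

    def test_noiseless_targets_track_tf_exactly(self):
        (motifs, truth), _ = self._net(driver_slope=1.0, driver_noise_sd=0.0)
        gene_idx = {g: i for i, g in enumerate(truth.genes)}
        for tf, target, slope in truth.tf_edges:
            if slope > 0:
                np.testing.assert_allclose(truth.effect[gene_idx[target]],
                                           truth.effect[gene_idx[tf]])

    def test_no_drivers_means_no_planted_slopes(self):
        (motifs, truth), _ = self._net(n_driver_tfs=0)
        assert all(slope == 0.0 for _, _, slope in truth.tf_edges)

    def test_driver_targets_correlate_more_than_nondriver(self):
        (motifs, truth), _ = self._net(driver_slope=0.8, driver_noise_sd=0.3)
        gene_idx = {g: i for i, g in enumerate(truth.genes)}
        rs = {True: [], False: []}
        for tf, target, slope in truth.tf_edges:
            r = np.corrcoef(truth.effect[gene_idx[tf]],
                            truth.effect[gene_idx[target]])[0, 1]
            if np.isfinite(r):
                rs[slope > 0].append(abs(r))
        assert np.mean(rs[True]) > np.mean(rs[False])

    def test_every_target_annotated_with_its_tf_motif(self):
        (motifs, truth), _ = self._net()
        annotated = {t for d in motifs.values() for t in d["targets"]}
        assert {t for _, t, _ in truth.tf_edges} <= annotated

    def test_too_many_targets_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_genes=50, n_tfs=10, targets_per_tf=10, seed=0)


class TestPslFixture:
    def test_zero_exons_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_psl_fixture(0, seed=1)

    def test_identity_below_threshold_labelled_drop(self):
        fx = sim.simulate_psl_fixture(120, seed=1)
        low = fx.truth[fx.truth["scenario"] == "low_identity"]
        assert len(low) and (~low["keep"]).all()
        assert (low["reason"] == "low_identity").all()

    def test_same_seed_byte_identical_psl(self, tmp_path):
        paths = []
        for i in (1, 2):
            fx = sim.simulate_psl_fixture(100, seed=9)
            p = tmp_path / f"fx{i}.psl"
            eio.write_psl(p, fx.forward)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_truth_covers_all_reason_codes(self):
        fx = sim.simulate_psl_fixture(500, seed=2)
        reasons = set(fx.truth.loc[~fx.truth["keep"], "reason"])
        assert reasons == {"low_identity", "indel", "reciprocal-human",
                           "reciprocal-chimp", "no-reciprocal-hit"}


def test_hybrid_allele_conservation(small_truth, small_config):
    """Re-simulating totals: human + chimp allele counts are the NB totals."""
    hyb = sim.simulate_hybrid_cells(small_truth, small_config)
    total = (hyb.hybrid_human + hyb.hybrid_chimp)
    assert (sp.csr_matrix(total).data >= 0).all()
    assert hyb.hybrid_human.shape == hyb.hybrid_chimp.shape


def test_write_study_round_trip(tmp_path, small_study, small_truth,
                                small_config):
    hyb = sim.simulate_hybrid_cells(small_truth, small_config)
    small_study.hybrid_human = hyb.hybrid_human
    small_study.hybrid_chimp = hyb.hybrid_chimp
    small_study.hybrid_meta = hyb.hybrid_meta
    sim.write_study(small_study, tmp_path)
    mat, barcodes, features = eio.read_mtx(tmp_path / "diploid")
    assert (mat != small_study.counts).nnz == 0
    assert features == small_truth.genes
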