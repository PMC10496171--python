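"""Correlation-motif joint DE: EM behaviour, classification rules and
cell-level motif scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logsumexp

from ebcomp import cormotif as cm
from ebcomp.validation import simulate_tstats


def _tstats(rng, g=800, c=3, frac_de=0.3, mu=4.0, df=12.0):
    de_mask = rng.random((g, c)) < frac_de
    t = rng.standard_t(df, (g, c)) + np.where(
        de_mask, mu * rng.choice([-1, 1], (g, c)), 0.0)
    tm = pd.DataFrame(t, index=[f"g{i}" for i in range(g)],
                      columns=[f"ct{j}" for j in range(c)])
    return cm.TStatMatrix(t=tm, df=pd.Series(df, index=tm.columns)), de_mask


class TestEm:
    def test_loglik_nondecreasing(self, rng):
        ts, _ = _tstats(rng)
        model = cm.fit_cormotif_em(ts, K=2, n_starts=3, seed=0)
        assert np.all(np.diff(model.loglik_trace) >= -1e-6)

    def test_responsibilities_normalized(self, rng):
        ts, _ = _tstats(rng)
        model = cm.fit_cormotif_em(ts, K=3, n_starts=2, seed=0)
        np.testing.assert_allclose(model.gene_motif_post.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert model.pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_needs_enough_genes(self, rng):
        ts, _ = _tstats(rng, g=30)
        with pytest.raises(ValueError):
            cm.fit_cormotif_em(ts, K=4)

    def test_na_cells_are_neutral(self, rng):
        ts, _ = _tstats(rng)
        t2 = ts.t.copy()
        t2.iloc[:, 2] = np.nan
        ts2 = cm.TStatMatrix(t=t2, df=ts.df)
        model = cm.fit_cormotif_em(ts2, K=2, n_starts=2, seed=0)
        assert model.de_post.iloc[:, 2].isna().all()
        assert np.isfinite(model.loglik)

    def test_single_condition_matches_scalar_em_oracle(self, rng):
        # with C=1 the K-component model collapses to a two-component
        # mixture whose only free parameter is w = sum_k pi_k q_k; an
        # independent scalar EM over w must reach the same log-likelihood
        ts, _ = _tstats(rng, g=1500, c=1, frac_de=0.25)
        model = cm.fit_cormotif_em(ts, K=2, n_starts=8, seed=0, tol=1e-10,
                                   max_iter=3000)
        lf0, lf1, _ = cm._log_densities(ts.t, ts.df, cm.V_GRID)
        f0, f1 = np.exp(lf0[:, 0]), np.exp(lf1[:, 0])
        w = 0.5
        for _ in range(5000):
            post = w * f1 / (w * f1 + (1 - w) * f0)
            w_new = post.mean()
            if abs(w_new - w) < 1e-14:
                break
            w = w_new
        oracle_ll = float(np.log(w * f1 + (1 - w) * f0).sum())
        assert model.loglik == pytest.approx(oracle_ll, abs=1e-6)

    def test_label_permutation_leaves_de_post_unchanged(self, rng):
        ts, _ = _tstats(rng)
        m = cm.fit_cormotif_em(ts, K=3, n_starts=2, seed=0)
        # recompute de_post from permuted parameters
        lf0, lf1, obs = cm._log_densities(ts.t, ts.df, cm.V_GRID)
        e = np.exp(np.clip(lf1 - lf0, -500, 500))
        perm = [2, 0, 1]
        q, pi = m.Q[perm], m.pi[perm]
        qe = q[None] * e[:, None, :]
        a = (1 - q)[None] + qe
        lr = np.log(pi)[None] + np.log(a).sum(2)
        r = np.exp(lr - logsumexp(lr, axis=1)[:, None])
        de_post = (r[:, :, None] * (qe / a)).sum(1)
        np.testing.assert_allclose(de_post, m.de_post.to_numpy(), atol=1e-12)


class TestSelectK:
    def test_reports_bic_for_all_k(self, rng):
        ts, _ = _tstats(rng, g=600)
        model = cm.select_k_bic(ts, [1, 2, 3], n_starts=2, seed=0,
                                tol=1e-3, max_iter=100)
        assert set(model.bic_by_k) == {1, 2, 3}
        assert all(np.isfinite(v) for v in model.bic_by_k.values())

    def test_single_motif_truth_selects_one(self, rng):
        q = np.array([[0.3, 0.3, 0.3]])
        ts, _, _ = simulate_tstats(rng, 1200, q=q, pi=np.array([1.0]))
        model = cm.select_k_bic(ts, [1, 2, 3], n_starts=3, seed=0,
                                tol=1e-3, max_iter=150)
        assert model.K == 1

    def test_empty_range_rejected(self, rng):
        ts, _ = _tstats(rng)
        with pytest.raises(ValueError):
            cm.select_k_bic(ts, [])


class TestClassification:
    def _model(self, de_post, membership=None):
        de_post = pd.DataFrame(de_post)
        de_post.index = [f"g{i}" for i in range(len(de_post))]
        k = 2
        gm = membership if membership is not None else pd.DataFrame(
            np.full((len(de_post), k), 1.0 / k), index=de_post.index,
            columns=["motif0", "motif1"])
        return cm.MotifModel(K=k, Q=np.zeros((k, de_post.shape[1])),
                             pi=np.full(k, 0.5), loglik=0.0, bic=0.0,
                             gene_motif_post=gm, de_post=de_post)

    def test_zero_posterior_no_calls(self):
        calls, n = cm.classify_de(self._model(np.zeros((5, 3))))
        assert not calls.to_numpy().any() and (n == 0).all()

    def test_threshold_zero_calls_everything(self):
        calls, _ = cm.classify_de(self._model(np.full((4, 2), 0.1)),
                                  threshold=0.0)
        assert calls.to_numpy().all()

    def test_restricted_de_rules(self):
        model = self._model(np.array([[0.99, 0.02], [0.99, 0.99],
                                      [0.99, 0.02]]))
        umi = {s: pd.DataFrame([[500, 150], [500, 500], [500, 50]],
                               index=model.de_post.index,
                               columns=model.de_post.columns)
               for s in ("human", "chimp")}
        out = cm.find_restricted_de(model, umi)
        # g0 qualifies; g1 is DE everywhere; g2's conserved cell type is
        # under-expressed
        assert list(out["gene"]) == ["g0"]
        assert out.loc[0, "de_celltypes"] == "0"
        assert out.loc[0, "conserved_celltypes"] == "1"

    def test_conserved_sets(self):
        de_post = np.array([[0.99, 0.99], [0.01, 0.01], [0.01, 0.01]])
        model = self._model(de_post)
        umi = {s: pd.DataFrame([[500, 500], [500, 500], [10, 10]],
                               index=model.de_post.index,
                               columns=model.de_post.columns)
               for s in ("human", "chimp")}
        fits = {"ct0": pd.DataFrame({
            "gene": model.de_post.index,
            "log2fc": [2.0, 0.0, 0.0],
            "se": [0.1, 0.1, 0.1],
            "df": [10.0] * 3})}
        out = cm.classify_conserved(model, umi, fits, min_celltypes=2)
        assert out.never_de == ["g1"]           # g2 fails the UMI gate
        assert "g0" not in out.effect_bounded   # confidently above bound
        assert out.conserved == ["g1"]


class TestCellScores:
    def test_zscore_properties(self, rng):
        genes = [f"g{i}" for i in range(40)]
        resid = pd.DataFrame(rng.normal(0, 1, (100, 40)), columns=genes)
        membership = pd.DataFrame(rng.dirichlet(np.ones(3), 40),
                                  index=genes,
                                  columns=["motif0", "motif1", "motif2"])
        model = cm.MotifModel(K=3, Q=np.zeros((3, 2)), pi=np.ones(3) / 3,
                              loglik=0.0, bic=0.0,
                              gene_motif_post=membership,
                              de_post=pd.DataFrame(np.zeros((40, 2)),
                                                   index=genes))
        scores, flags = cm.cormotif_cell_scores(resid, model)
        assert not flags.any()
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(scores.to_numpy().std(axis=0), 1.0,
                                   atol=1e-9)

    def test_zero_membership_motif_flagged(self, rng):
        genes = [f"g{i}" for i in range(10)]
        resid = pd.DataFrame(rng.normal(0, 1, (20, 10)), columns=genes)
        membership = pd.DataFrame(
            np.column_stack([np.ones(10), np.zeros(10)]), index=genes,
            columns=["motif0", "motif1"])
        model = cm.MotifModel(K=2, Q=np.zeros((2, 1)), pi=np.array([1.0, 0.0]),
                              loglik=0.0, bic=0.0, gene_motif_post=membership,
                              de_post=pd.DataFrame(np.zeros((10, 1)),
                                                   index=genes))
        scores, flags = cm.cormotif_cell_scores(resid, model)
        assert flags["motif1"]
        assert (scores["motif1"] == 0.0).all()

    def test_elevated_cells_score_higher(self, rng):
        genes = [f"g{i}" for i in range(60)]
        membership = pd.DataFrame(
            np.column_stack([np.repeat([1.0, 0.0], 30),
                             np.repeat([0.0, 1.0], 30)]),
            index=genes, columns=["motif0", "motif1"])
        resid = rng.normal(0, 1, (200, 60))
        hot = np.arange(100)  # first 100 cells elevated on motif0 genes
        resid[np.ix_(hot, np.arange(30))] += 1.5
        model = cm.MotifModel(K=2, Q=np.zeros((2, 1)), pi=np.array([0.5, 0.5]),
                              loglik=0.0, bic=0.0, gene_motif_post=membership,
                              de_post=pd.DataFrame(np.zeros((60, 1)),
                                                   index=genes))
        scores, _ = cm.cormotif_cell_scores(
            pd.DataFrame(resid, columns=genes), model)
        s = scores["motif0"].to_numpy()
        labels = np.zeros(200, bool)
        labels[hot] = True
        auc = stats.mannwhitneyu(s[labels], s[~labels]).statistic / (100 * 100)
        assert auc >= 0.9

    def test_no_shared_genes_rejected(self, rng):
        model = cm.MotifModel(K=1, Q=np.zeros((1, 1)), pi=np.ones(1),
                              loglik=0.0, bic=0.0,
                              gene_motif_post=pd.DataFrame({"motif0": [1.0]},
                                                           index=["gX"]),
                              de_post=pd.DataFrame(np.zeros((1, 1)),
                                                   index=["gX"]))
        with pytest.raises(ValueError):
            cm.cormotif_cell_scores(
                pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"]),
                model)


def test_condition_tstats_deterministic_and_ranked(small_pseudobulk,
                                                   small_truth):
    ts1 = cm.condition_tstats(small_pseudobulk)
    ts2 = cm.condition_tstats(small_pseudobulk)
    pd.testing.assert_frame_equal(ts1.t, ts2.t)
    # planted DE genes carry stochastically larger |t|
    tall = ts1.t.abs().mean(axis=1)
    de_genes = [g for g, d in zip(small_truth.genes,
                                  small_truth.de_indicator.any(axis=1)) if d]
    de_in = tall.index.intersection(de_genes)
    null_in = tall.index.difference(de_genes)
    assert tall[de_in].median() > tall[null_in].median()
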