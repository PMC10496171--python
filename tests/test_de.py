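"""Precision weights, the weighted mixed model, moderation, BH and the
effect-bound probability."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ebcomp import de


def _meta(n_per_species=9, individuals=3, replicates=3):
    rows = []
    for spc in ("human", "chimp"):
        for i in range(individuals):
            for r in range(replicates):
                rows.append({"species": spc,
                             "individual": f"{spc[0]}{i}",
                             "replicate": f"r{r}"})
    return pd.DataFrame(rows)


class TestVoomWeights:
    def test_flat_trend_gives_equal_weights(self):
        counts = np.full((50, 6), 100.0)
        x = np.column_stack([np.ones(6), np.repeat([-0.5, 0.5], 3)])
        w, _ = de.voom_weights(counts, np.ones(6), x)
        assert np.allclose(w, w[0, 0])

    def test_weights_positive_finite(self, rng):
        counts = rng.poisson(rng.gamma(1.5, 20.0, (200, 8))) + 1
        x = np.column_stack([np.ones(8), np.repeat([-0.5, 0.5], 4)])
        w, _ = de.voom_weights(counts, np.ones(8), x)
        assert np.all(np.isfinite(w)) and np.all(w > 0)

    def test_weights_increase_with_expression(self, rng):
        # NB counts: low-expression genes are noisier on the log scale, so
        # their precision weights sit below the high-expression plateau
        mu = np.repeat([2.0, 500.0], 150)
        counts = rng.poisson(rng.gamma(5.0, mu[:, None] / 5.0, (300, 8)))
        x = np.column_stack([np.ones(8), np.repeat([-0.5, 0.5], 4)])
        w, _ = de.voom_weights(counts, np.ones(8), x)
        assert w[:150].mean() < w[150:].mean()


class TestMixedModel:
    def test_structural_degenerate_limit_matches_wls(self, rng):
        # one individual and one replicate level: no random components, the
        # fit must equal weighted OLS
        meta = pd.DataFrame({"species": ["human"] * 4 + ["chimp"] * 4,
                             "individual": ["i"] * 8,
                             "replicate": ["r"] * 8})
        y = rng.normal(0, 1, (20, 8))
        w = rng.uniform(0.5, 2.0, (20, 8))
        fit = de.fit_mixed_de(y, w, meta)
        x = np.column_stack([np.ones(8), np.repeat([-0.5, 0.5], 4)])
        for gi in range(20):
            ref = sm.WLS(y[gi], x, weights=w[gi]).fit()
            assert fit["log2fc"].iloc[gi] == pytest.approx(ref.params[1],
                                                           abs=1e-9)
            assert fit["se"].iloc[gi] == pytest.approx(ref.bse[1], abs=1e-9)

    def test_zero_variance_genes_match_wls_at_floor(self, rng):
        # exactly balanced group structure with no group signal: the REML
        # variance ratios hit the floor and the fit reduces to WLS
        meta = _meta()
        x = np.column_stack([np.ones(18),
                             meta["species"].map({"human": -0.5,
                                                  "chimp": 0.5})])
        noise = rng.normal(0, 0.1, (5, 18))
        noise -= noise.mean(axis=1, keepdims=True)
        y = 1.0 * x[:, 1][None, :] + noise
        w = np.ones((5, 18))
        fit = de.fit_mixed_de(y, w, meta)
        for gi in range(5):
            ref = sm.WLS(y[gi], x, weights=w[gi]).fit()
            # beta agrees tightly; se within the variance-ratio floor slack
            assert fit["log2fc"].iloc[gi] == pytest.approx(ref.params[1],
                                                           rel=1e-6)

    def test_recovers_planted_contrast(self, rng):
        meta = _meta()
        x_species = meta["species"].map({"human": -0.5, "chimp": 0.5}).to_numpy()
        indiv = pd.factorize(meta["individual"])[0]
        g = 80
        y = (1.5 * x_species[None, :]
             + rng.normal(0, 0.2, (g, 6))[:, indiv]
             + rng.normal(0, 0.2, (g, 18)))
        fit = de.fit_mixed_de(y, np.ones((g, 18)), meta)
        assert fit["log2fc"].mean() == pytest.approx(1.5, abs=0.1)
        assert (fit["df"] <= 16.0 + 1e-9).all() and (fit["df"] >= 1.0).all()

    def test_t_equals_fc_over_se(self, rng):
        meta = _meta()
        y = rng.normal(0, 1, (10, 18))
        fit = de.fit_mixed_de(y, np.ones((10, 18)), meta)
        np.testing.assert_allclose(fit["t"], fit["log2fc"] / fit["se"],
                                   atol=1e-9)

    def test_covariates_accepted(self, rng):
        meta = _meta()
        cov = rng.normal(0, 1, 18)
        fit = de.fit_mixed_de(rng.normal(0, 1, (5, 18)), np.ones((5, 18)),
                              meta, covariates=cov)
        assert len(fit) == 5

    def test_too_few_samples_rejected(self):
        meta = pd.DataFrame({"species": ["human", "chimp"],
                             "individual": ["a", "b"],
                             "replicate": ["r", "r"]})
        with pytest.raises(ValueError):
            de.fit_mixed_de(np.zeros((3, 2)), np.ones((3, 2)), meta)


class TestModeration:
    def test_identical_variances_unchanged(self, rng):
        fit = pd.DataFrame({"gene": [f"g{i}" for i in range(30)],
                            "log2fc": rng.normal(0, 1, 30),
                            "sigma": np.full(30, 0.7),
                            "se_unit": np.full(30, 0.3),
                            "df": np.full(30, 12.0),
                            "df_resid": np.full(30, 12.0)})
        fit["se"] = fit["sigma"] * fit["se_unit"]
        out = de.moderate_stats(fit)
        np.testing.assert_allclose(out["se"], fit["se"], rtol=1e-9)

    def test_chisquare_prior_recovered(self, rng):
        d0, s0sq, d, g = 8.0, 0.04, 16.0, 5000
        sigma2 = s0sq * d0 / rng.chisquare(d0, g)
        s2 = sigma2 * rng.chisquare(d, g) / d
        d0_hat, s0_hat = de.estimate_variance_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.10)
        assert s0_hat == pytest.approx(s0sq, rel=0.10)

    def test_moderated_shrinks_toward_prior(self, rng):
        g = 400
        fit = pd.DataFrame({"gene": [f"g{i}" for i in range(g)],
                            "log2fc": rng.normal(0, 1, g),
                            "sigma": np.sqrt(0.25 * rng.chisquare(10, g) / 10
                                             * rng.lognormal(0, 0.5, g)),
                            "se_unit": np.full(g, 0.3),
                            "df": np.full(g, 10.0),
                            "df_resid": np.full(g, 10.0)})
        fit["se"] = fit["sigma"] * fit["se_unit"]
        out = de.moderate_stats(fit)
        assert out["moderated"].all()
        # shrinkage reduces the spread of the variances
        assert np.var(np.log(out["se"])) < np.var(np.log(fit["se"]))


class TestBhAdjust:
    def test_stepup_hand_computation(self):
        np.testing.assert_allclose(de.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_and_degenerate(self):
        assert de.bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(de.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_nan_passthrough(self):
        out = de.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    def test_fdr_at_least_p(self, rng):
        p = rng.uniform(0, 1, 200)
        assert np.all(de.bh_adjust(p) >= p - 1e-12)


class TestEffectBound:
    def test_matches_quadrature(self):
        from scipy.integrate import quad
        for b, se, df in [(0.0, 0.1, 10.0), (0.5, 0.1, 30.0),
                          (-0.8, 0.4, 5.0), (0.2, 1.5, 20.0)]:
            got = de.prob_effect_in_bound(b, se, df, bound=0.5)
            ref, _ = quad(lambda x: stats.t.pdf((x - b) / se, df) / se,
                          -0.5, 0.5, epsabs=1e-12, limit=200)
            assert got == pytest.approx(ref, abs=1e-8)

    def test_at_bound_half(self):
        assert de.prob_effect_in_bound(0.5, 0.01, 30.0) == pytest.approx(
            0.5, abs=1e-3)

    def test_huge_se_goes_to_zero(self):
        assert de.prob_effect_in_bound(0.0, 1e6, 10.0) < 1e-5

    def test_zero_se_indicator(self):
        assert de.prob_effect_in_bound(0.3, 0.0, 10.0) == 1.0
        assert de.prob_effect_in_bound(0.7, 0.0, 10.0) == 0.0


def test_bigger_effect_bigger_t(rng):
    """Increasing a planted effect never decreases the median |t| (paired
    noise)."""
    meta = _meta()
    x_species = meta["species"].map({"human": -0.5, "chimp": 0.5}).to_numpy()
    noise = rng.normal(0, 0.5, (100, 18))
    meds = []
    for beta in (0.0, 0.5, 1.0, 2.0):
        y = beta * x_species[None, :] + noise
        fit = de.fit_fixed_de(y, np.ones_like(y), meta)
        meds.append(np.median(np.abs(fit["t"])))
    assert all(a <= b + 1e-9 for a, b in zip(meds, meds[1:]))
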