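"""ZTNB likelihood and the three genotype-comparison models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ibexniche as ix
from ibexniche.models import (
    _fit_lmm_random_intercept,
    fit_lesion_size,
    fit_pc1,
    fit_tumor_fraction,
    ztnb_loglik,
    ztpoisson_loglik,
)


def naive_ztnb_loglik(y, mu, theta):
    """Oracle: direct pmf-ratio form via scipy.stats.nbinom."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    p = theta / (theta + mu)
    pmf = stats.nbinom.pmf(y, theta, p)
    p0 = stats.nbinom.pmf(0, theta, p)
    return float(np.sum(np.log(pmf / (1.0 - p0))))


class TestZTNBLoglik:
    def test_hand_value_y1_mu1_theta1(self):
        # NB(1;1,1)=1/4, NB(0;1,1)=1/2 -> ln(0.25/0.5)
        assert ztnb_loglik([1], [1.0], 1.0) == pytest.approx(np.log(0.5),
                                                             abs=1e-9)

    def test_matches_naive_pmf_ratio_on_grid(self):
        for mu in (0.5, 1.0, 5.0, 20.0):
            for theta in (0.3, 1.0, 5.0):
                y = np.arange(1, 11)
                mine = ztnb_loglik(y, mu, theta)
                oracle = naive_ztnb_loglik(y, mu, theta)
                assert mine == pytest.approx(oracle, abs=1e-8)

    def test_poisson_limit(self):
        y = np.arange(1, 21)
        mu = 3.7
        diff = abs(ztnb_loglik(y, mu, 1e6) - ztpoisson_loglik(y, mu)) / len(y)
        assert diff < 1e-3

    def test_zero_response_rejected(self):
        with pytest.raises(ValueError):
            ztnb_loglik([0, 1], [1.0, 1.0], 1.0)

    def test_random_parameter_draws_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.integers(1, 60, 5)
            mu = rng.uniform(0.2, 40.0, 5)
            theta = rng.uniform(0.2, 30.0)
            assert ztnb_loglik(y, mu, theta) == pytest.approx(
                naive_ztnb_loglik(y, mu, theta), abs=1e-8)


class TestFitLesionSize:
    def test_parameter_recovery(self):
        sizes = ix.ztnb_rvs(5.0, 2.0, 2000, rng=7)
        df = pd.DataFrame({"size": sizes, "genotype": "control",
                           "sample_id": "control_1"})
        fit = fit_lesion_size(df, grouping_mode="none")
        assert np.exp(fit.coef("intercept")) == pytest.approx(5.0, rel=0.05)
        assert fit.dispersion == pytest.approx(2.0, rel=0.15)

    def test_matches_glmmtmb_reference_fit(self):
        """Frozen reference: glmmTMB (truncated_nbinom2, size ~ genotype)
        fitted to this exact seeded dataset gives the values below."""
        df = ix.simulate_lesion_sizes(10.0, 4.0, 2.0, 60, seed=42)
        fit = fit_lesion_size(df, grouping_mode="none")
        assert fit.coef("intercept") == pytest.approx(2.1617696973, abs=1e-4)
        assert fit.coef("genotype_ko") == pytest.approx(-0.7079740917, abs=1e-4)
        assert fit.params.loc["intercept", "se"] == pytest.approx(
            0.08943763482, abs=1e-4)
        assert fit.params.loc["genotype_ko", "se"] == pytest.approx(
            0.13589173912, abs=1e-4)
        assert fit.dispersion == pytest.approx(2.860055, rel=1e-3)
        assert fit.loglik == pytest.approx(-323.9128, abs=1e-3)

    def test_bias_shrinks_with_sample_size(self):
        errs = []
        for n in (100, 500, 2000):
            mu_err = []
            for s in range(20):
                sizes = ix.ztnb_rvs(5.0, 2.0, n, rng=1000 + 20 * n + s)
                df = pd.DataFrame({"size": sizes, "genotype": "control",
                                   "sample_id": "c1"})
                f = fit_lesion_size(df, grouping_mode="none", n_starts=2)
                mu_err.append(np.exp(f.coef("intercept")) - 5.0)
            errs.append(abs(np.mean(mu_err)))
        assert errs[2] < errs[0]

    def test_zero_sizes_rejected(self):
        df = pd.DataFrame({"size": [0, 2, 3] * 5, "genotype": "control",
                           "sample_id": "c1"})
        with pytest.raises(ValueError):
            fit_lesion_size(df)

    def test_seed_reproducibility(self):
        df = ix.simulate_lesion_sizes(16.8, 3.8, 2.0, 100, seed=3,
                                      truncated_means=True)
        f1 = fit_lesion_size(df, seed=5)
        f2 = fit_lesion_size(df, seed=5)
        pd.testing.assert_frame_equal(f1.params, f2.params)

    def test_observation_order_invariance(self):
        df = ix.simulate_lesion_sizes(16.8, 3.8, 2.0, 100, seed=4,
                                      truncated_means=True)
        f1 = fit_lesion_size(df)
        perm = np.random.default_rng(0).permutation(len(df))
        f2 = fit_lesion_size(df.iloc[perm].reset_index(drop=True))
        assert np.allclose(f1.params["coef"], f2.params["coef"], atol=1e-5)


class TestFitTumorFraction:
    def test_null_effect_near_zero(self):
        flags = ix.simulate_tumor_flags(p_control=0.04, p_ko=0.04, seed=0)
        fit = fit_tumor_fraction(flags, grouping_mode="none")
        assert abs(fit.coef("genotype_ko")) < 0.2
        assert fit.pvalue("genotype_ko") > 0.05

    def test_recovers_generator_log_odds(self):
        truth = np.log((0.02 / 0.98) / (0.05 / 0.95))
        flags = ix.simulate_tumor_flags(seed=1)
        fit = fit_tumor_fraction(flags)  # random intercept default
        se = fit.params.loc["genotype_ko", "se"]
        assert abs(fit.coef("genotype_ko") - truth) < 3 * se

    def test_fixed_sample_close_to_random_intercept(self):
        flags = ix.simulate_tumor_flags(seed=2)
        a = fit_tumor_fraction(flags, grouping_mode="fixed_sample")
        b = fit_tumor_fraction(flags, grouping_mode="random_intercept")
        assert a.coef("genotype_ko") == pytest.approx(b.coef("genotype_ko"),
                                                      rel=0.10)

    def test_complete_separation_raises(self):
        flags = ix.simulate_tumor_flags(seed=3)
        flags.loc[flags["genotype"] == "ko", "is_tumor"] = False
        with pytest.raises(ValueError, match="separation"):
            fit_tumor_fraction(flags)

    def test_single_sample_per_genotype_rejected(self):
        flags = ix.simulate_tumor_flags(n_samples_per_genotype=1, seed=0)
        with pytest.raises(ValueError):
            fit_tumor_fraction(flags)


class TestRandomInterceptLMM:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        g = np.repeat(np.arange(8), 25)
        x = rng.normal(size=200)
        u = rng.normal(0, 0.7, 8)
        y = 1.0 + 0.5 * x + u[g] + rng.normal(0, 1.0, 200)
        X = np.column_stack([np.ones(200), x])
        beta, ses, llf, re_sd = _fit_lmm_random_intercept(y, X, g)
        ref = sm.MixedLM(y, X, groups=g).fit(reml=False)
        assert np.allclose(beta, ref.fe_params, atol=1e-5)
        assert llf == pytest.approx(float(ref.llf), abs=1e-5)
        assert re_sd == pytest.approx(
            float(np.sqrt(np.asarray(ref.cov_re)[0, 0])), abs=1e-4)

    def test_boundary_collapses_to_ols(self):
        rng = np.random.default_rng(6)
        g = np.repeat(np.arange(6), 30)
        x = rng.normal(size=180)
        y = 2.0 - 0.3 * x + rng.normal(0, 1.0, 180)
        X = np.column_stack([np.ones(180), x])
        beta, _, _, re_sd = _fit_lmm_random_intercept(y, X, g)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert re_sd < 0.15
        assert np.allclose(beta, ols, atol=0.02)


class TestFitPC1:
    def _scores(self, seed, n=150):
        comp = ix.simulate_lesion_compositions(n, seed=seed)
        table = ix.build_niche_table(comp)
        return ix.analyze_niches(table).scores

    def test_location_invariance(self):
        sc = self._scores(0)
        f1 = fit_pc1(sc)
        sc2 = sc.copy()
        sc2["PC1"] = sc2["PC1"] + 17.0
        f2 = fit_pc1(sc2)
        for term in ("size", "size:genotype_ko"):
            assert f1.coef(term) == pytest.approx(f2.coef(term), abs=1e-8)

    def test_detects_planted_effects(self):
        f = fit_pc1(self._scores(1))
        assert f.pvalue("size") < 0.05
        assert f.pvalue("genotype_ko") < 0.05

    def test_single_genotype_drops_terms_with_warning(self):
        sc = self._scores(2)
        sc = sc[sc["genotype"] == "control"]
        with pytest.warns(UserWarning, match="genotype"):
            f = fit_pc1(sc)
        assert "genotype_ko" not in f.params.index

    def test_null_pvalues_roughly_uniform(self):
        """With PC1 scrambled, size/genotype p-values are null-calibrated."""
        rng = np.random.default_rng(7)
        pvals = []
        sc = self._scores(3, n=120)
        for _ in range(200):
            s2 = sc.copy()
            s2["PC1"] = rng.permutation(s2["PC1"].to_numpy())
            f = fit_pc1(s2, grouping_mode="none")
            pvals.append(f.pvalue("genotype_ko"))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_raw_size_scale_option(self):
        f = fit_pc1(self._scores(4), size_scale="raw")
        assert f.metadata["size_scale"] == "raw"
        assert "size" in f.params.index
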