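"""Negative-binomial Ricker likelihood and parameter estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

import coexar as cx
from coexar.ricker import ALL_PLOTS, CommunityParams, FLAG_ESTIMATED


def make_params(species, log_lambda, alpha, dispersion, g=0.6, s=0.4, **kw):
    n = len(species)
    return CommunityParams(
        year=1, plot=ALL_PLOTS, species=tuple(species),
        log_lambda=np.asarray(log_lambda, dtype=float),
        alpha=np.asarray(alpha, dtype=float),
        g=np.full(n, g), s=np.full(n, s),
        dispersion=np.asarray(dispersion, dtype=float), **kw,
    )


def obs_frame(rows, species):
    cols = ["year", "plot", "subplot", "focal", "seeds"] + [f"n_{sp}" for sp in species]
    return pd.DataFrame(rows, columns=cols)


class TestLoglik:
    def test_matches_independent_pmf(self):
        """Single row at the mean: equals scipy's NB pmf evaluated directly."""
        params = make_params(["A"], [1.0], [[0.0]], [2.5])
        obs = obs_frame([[1, 1, 1, "A", 3, 0]], ["A"])
        mu, k = np.e, 2.5
        expected = nbinom.logpmf(3, k, k / (k + mu))
        assert cx.neg_binomial_ricker_loglik(params, obs) == pytest.approx(expected)

    def test_row_additivity(self):
        params = make_params(["A"], [1.2], [[0.05]], [3.0])
        one = obs_frame([[1, 1, 1, "A", 4, 2]], ["A"])
        two = obs_frame([[1, 1, 1, "A", 4, 2]] * 2, ["A"])
        assert cx.neg_binomial_ricker_loglik(params, two) == pytest.approx(
            2 * cx.neg_binomial_ricker_loglik(params, one))

    def test_zero_neighbors_nullify_alpha(self):
        obs = obs_frame([[1, 1, 1, "A", 4, 0], [1, 1, 2, "A", 1, 0]], ["A"])
        with_alpha = make_params(["A"], [1.2], [[0.4]], [3.0])
        without = make_params(["A"], [1.2], [[0.0]], [3.0])
        assert cx.neg_binomial_ricker_loglik(with_alpha, obs) == pytest.approx(
            cx.neg_binomial_ricker_loglik(without, obs))

    def test_unknown_focal_rejected(self):
        params = make_params(["A"], [1.0], [[0.1]], [2.0])
        obs = obs_frame([[1, 1, 1, "B", 3, 0]], ["A"])
        with pytest.raises(ValueError, match="not present"):
            cx.neg_binomial_ricker_loglik(params, obs)

    def test_overflow_reported_with_row(self):
        params = make_params(["A"], [1.0], [[-500.0]], [2.0])
        obs = obs_frame([[1, 1, 1, "A", 3, 5]], ["A"])
        with pytest.raises(FloatingPointError, match="row index"):
            cx.neg_binomial_ricker_loglik(params, obs)


class TestHomogeneousFit:
    def test_intercept_only_equals_sample_mean(self):
        """With no neighbors ever, the NB MLE of lambda is the sample mean."""
        rng = np.random.default_rng(0)
        seeds = rng.negative_binomial(3, 3 / (3 + 12.0), 400)
        obs = obs_frame([[1, 1, 1, "A", int(y), 0] for y in seeds], ["A"])
        fit = cx.fit_homogeneous(obs, {"A": 0.6}, {"A": 0.4}, year=1)
        assert fit.log_lambda[0] == pytest.approx(np.log(seeds.mean()), abs=1e-4)
        # the never-observed self column is flagged and fixed at zero
        assert fit.fit_flags[0, 0] == "fixed_zero_unobserved"
        assert fit.alpha[0, 0] == 0.0

    def test_two_species_interaction_recovery(self):
        """alpha_12 = 0.2 truth recovered within 3 SE at n = 500."""
        rng = np.random.default_rng(14)
        n, k = 500, 3.0
        n_b = rng.poisson(2.0, n)
        n_a = rng.poisson(1.5, n)
        mu_a = 20.0 * np.exp(-0.2 * n_b - 0.05 * n_a)
        rows = [[1, 1, 1, "A", int(rng.negative_binomial(k, k / (k + m))), na, nb]
                for m, na, nb in zip(mu_a, n_a, n_b)]
        mu_b = 15.0 * np.exp(-0.1 * n_b)
        rows += [[1, 1, 1, "B", int(rng.negative_binomial(k, k / (k + m))), 0, int(nb)]
                 for m, nb in zip(mu_b, rng.poisson(2.0, n))]
        obs = obs_frame(rows, ["A", "B"])
        fit = cx.fit_homogeneous(obs, {"A": 0.6, "B": 0.6}, {"A": 0.4, "B": 0.4}, 1)
        i, j = fit.index("A"), fit.index("B")
        assert fit.fit_flags[i, j] == FLAG_ESTIMATED
        assert abs(fit.alpha[i, j] - 0.2) < 3 * fit.se_alpha[i, j]
        assert abs(fit.log_lambda[i] - np.log(20.0)) < 3 * fit.se_log_lambda[i]

    def test_fit_beats_truth_loglik(self, small_design, small_truth, small_obs):
        """MLE property: each species' fitted log-likelihood >= the truth's."""
        g = dict(zip(small_truth.species, small_truth.g))
        s = dict(zip(small_truth.species, small_truth.s))
        fit = cx.fit_homogeneous(small_obs, g, s, year=1)
        obs1 = small_obs[small_obs["year"] == 1]
        truth_params = make_params(
            small_truth.species, small_truth.log_lambda, small_truth.alpha,
            small_truth.dispersion)
        n_compared = 0
        for i, sp in enumerate(fit.species):
            if not fit.converged[i]:
                continue
            rows = obs1[obs1["focal"] == sp]
            truth_ll = cx.neg_binomial_ricker_loglik(truth_params, rows)
            assert fit.loglik[i] >= truth_ll - 1e-6, sp
            n_compared += 1
        assert n_compared >= 5

    def test_row_order_invariance(self, small_design, small_truth, small_obs):
        g = dict(zip(small_truth.species, small_truth.g))
        s = dict(zip(small_truth.species, small_truth.s))
        fit = cx.fit_homogeneous(small_obs, g, s, year=2)
        shuffled = small_obs.sample(frac=1.0, random_state=5).reset_index(drop=True)
        fit2 = cx.fit_homogeneous(shuffled, g, s, year=2)
        assert fit.species == fit2.species
        np.testing.assert_allclose(fit.log_lambda, fit2.log_lambda, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(fit.alpha, fit2.alpha, rtol=1e-6, atol=1e-6)

    def test_wald_interval_coverage(self):
        """95% intervals for log-lambda cover the truth at a sane rate."""
        rng = np.random.default_rng(21)
        hits = total = 0
        for _ in range(20):
            k, lam, a = 2.5, 18.0, 0.08
            n = 250
            nn = rng.poisson(1.5, n)
            mu = lam * np.exp(-a * nn)
            seeds = rng.negative_binomial(k, k / (k + mu))
            obs = obs_frame(
                [[1, 1, 1, "A", int(y), int(m)] for y, m in zip(seeds, nn)], ["A"])
            fit = cx.fit_homogeneous(obs, {"A": 0.6}, {"A": 0.4}, 1)
            half = 1.96 * fit.se_log_lambda[0]
            hits += abs(fit.log_lambda[0] - np.log(lam)) <= half
            total += 1
        assert 0.85 <= hits / total <= 1.0


class TestHeterogeneousFit:
    @pytest.fixture(scope="class")
    def fits(self, small_design, small_truth, small_obs):
        g = dict(zip(small_truth.species, small_truth.g))
        s = dict(zip(small_truth.species, small_truth.s))
        pooled = cx.fit_homogeneous(small_obs, g, s, year=1)
        plot_fits = cx.fit_heterogeneous(small_obs, g, s, 1, 0.5, pooled=pooled)
        return pooled, plot_fits

    def test_zero_shrinkage_collapses_to_pooled(self, small_truth, small_obs, fits):
        pooled, _ = fits
        g = dict(zip(small_truth.species, small_truth.g))
        s = dict(zip(small_truth.species, small_truth.s))
        collapsed = cx.fit_heterogeneous(small_obs, g, s, 1, 0.0, pooled=pooled)
        for pfit in collapsed:
            for sp in pfit.species:
                i, j = pfit.index(sp), pooled.index(sp)
                assert pfit.log_lambda[i] == pooled.log_lambda[j]

    def test_single_plot_equals_pooled(self, small_truth, small_obs):
        g = dict(zip(small_truth.species, small_truth.g))
        s = dict(zip(small_truth.species, small_truth.s))
        one_plot = small_obs[small_obs["plot"] == 1]
        pooled = cx.fit_homogeneous(one_plot, g, s, 1)
        het = cx.fit_heterogeneous(one_plot, g, s, 1, 0.5, pooled=pooled)
        assert len(het) == 1
        for sp in het[0].species:
            i, j = het[0].index(sp), pooled.index(sp)
            assert het[0].log_lambda[i] == pytest.approx(pooled.log_lambda[j], abs=1e-4)
            np.testing.assert_allclose(
                het[0].alpha[i], pooled.alpha[j][
                    [pooled.index(sp2) for sp2 in het[0].species]], atol=1e-4)

    def test_absent_species_carry_no_estimate(self, small_obs, fits):
        _, plot_fits = fits
        obs1 = small_obs[small_obs["year"] == 1]
        for pfit in plot_fits:
            present = set(obs1[obs1["plot"] == pfit.plot]["focal"].unique())
            assert set(pfit.species) <= present

    def test_detects_injected_plot_variance(self):
        """Between-plot variance of fitted log-lambda rises with truth sd."""
        d = cx.StudyDesign(n_years=1, n_plots=6,
                           species_names=tuple(f"SP{i:02d}" for i in range(1, 7)))
        out = {}
        for sd, scen in [(0.0, "homogeneous"), (0.5, "heterogeneous")]:
            truth = cx.generate_ground_truth(d, scen, sd, seed=31)
            obs = cx.generate_observations(truth, d, 40, seed=32)
            g = dict(zip(truth.species, truth.g))
            s = dict(zip(truth.species, truth.s))
            pooled = cx.fit_homogeneous(obs, g, s, 1)
            het = cx.fit_heterogeneous(obs, g, s, 1, 0.5, pooled=pooled)
            var = []
            for sp in pooled.species:
                vals = [p.log_lambda[p.index(sp)] for p in het if sp in p.species]
                if len(vals) >= 3:
                    var.append(np.var(vals, ddof=1))
            out[sd] = float(np.mean(var))
        assert out[0.5] > 2.0 * out[0.0]


class TestParameterDraws:
    def test_draw_count_and_determinism(self, small_truth, small_obs):
        g = dict(zip(small_truth.species, small_truth.g))
        s = dict(zip(small_truth.species, small_truth.s))
        fit = cx.fit_homogeneous(small_obs, g, s, 1)
        draws = cx.draw_parameter_replicates(fit, n_draws=100, seed=6)
        assert len(draws) == 100
        again = cx.draw_parameter_replicates(fit, n_draws=100, seed=6)
        for d1, d2 in zip(draws, again):
            np.testing.assert_array_equal(d1.log_lambda, d2.log_lambda)
            np.testing.assert_array_equal(d1.alpha, d2.alpha)
        # fixed-zero coefficients never move
        fixed = fit.fit_flags != FLAG_ESTIMATED
        for d in draws[:10]:
            np.testing.assert_array_equal(d.alpha[fixed], fit.alpha[fixed])

    def test_zero_se_draws_equal_point_estimate(self, small_truth, small_obs):
        g = dict(zip(small_truth.species, small_truth.g))
        s = dict(zip(small_truth.species, small_truth.s))
        fit = cx.fit_homogeneous(small_obs, g, s, 1)
        fit.se_log_lambda = np.zeros_like(fit.se_log_lambda)
        fit.se_alpha = np.zeros_like(fit.se_alpha)
        for d in cx.draw_parameter_replicates(fit, n_draws=3, seed=7):
            np.testing.assert_array_equal(d.log_lambda, fit.log_lambda)
            np.testing.assert_array_equal(d.alpha, fit.alpha)

    def test_missing_se_rejected(self, small_truth):
        params = make_params(small_truth.species, small_truth.log_lambda,
                             small_truth.alpha, small_truth.dispersion)
        with pytest.raises(ValueError, match="standard errors"):
            cx.draw_parameter_replicates(params, 5, seed=0)
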