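"""Gibbs sampler, priors, diagnostics, and category-probability reporting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from expobayes.bayes_compliance import (
    Z95,
    CategoryScheme,
    MCMCSettings,
    ParameterSpace,
    PriorSpec,
    TruncationError,
    category_probabilities,
    convergence_report,
    derive_quantities,
    gelman_rubin,
    gibbs_sample,
    ig_shape_scale,
    log_sufficient_stats,
    summarize_posterior,
)

FAST = MCMCSettings(chains=2, iterations=3000, burn_in=500, seed=99)


class TestSufficientStats:
    def test_two_point_hand_computation(self):
        d = log_sufficient_stats([1.0, math.e**2])
        assert d.n == 2
        assert d.mean_log == pytest.approx(1.0)
        assert d.sd_log == pytest.approx(math.sqrt(2))
        assert d.sum_sq == pytest.approx(2.0)

    def test_all_equal_zero_spread(self):
        d = log_sufficient_stats([0.7, 0.7, 0.7])
        assert d.sd_log == 0.0
        assert d.sum_sq == 0.0

    def test_matched_synthetic_reproduces_published_row(self):
        """Moment-matched data for (n 18, gm 0.41, gsd 3.41) reduce exactly."""
        from expobayes.synthetic_data import GeneratorSpec, generate_matched_lognormal

        recs = generate_matched_lognormal(
            GeneratorSpec("Pump Attendant", 18, 0.41, 3.41, seed=3)
        )
        d = log_sufficient_stats([r.twa8h for r in recs])
        assert d.mean_log == pytest.approx(math.log(0.41), abs=1e-12)
        assert d.sd_log == pytest.approx(math.log(3.41), abs=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            log_sufficient_stats([1.0])


class TestIGShapeScale:
    @pytest.mark.parametrize(
        "n0,var,shape,rate,inv",
        [(5, 1.0, 2.0, 2.0, 0.5), (3, 2.0, 1.0, 2.0, 0.5)],
    )
    def test_both_printed_conventions(self, n0, var, shape, rate, inv):
        ig = ig_shape_scale(n0, var)
        assert ig.shape == pytest.approx(shape)
        assert ig.rate == pytest.approx(rate)
        assert ig.inv_rate == pytest.approx(inv)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(n0=st.floats(1.1, 50), var=st.floats(1e-3, 10))
    def test_rate_and_reciprocal_multiply_to_one(self, n0, var):
        ig = ig_shape_scale(n0, var)
        assert ig.rate * ig.inv_rate == pytest.approx(1.0, rel=1e-12)

    def test_prior_n_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            ig_shape_scale(1.0, 1.0)


class TestDeriveQuantities:
    def test_degenerate_point(self):
        assert derive_quantities(0.0, 0.0) == (1.0, 1.0, 1.0)

    def test_p95_closed_form_unit_sigma(self):
        _, _, p95 = derive_quantities(0.0, 1.0)
        assert p95 == pytest.approx(math.exp(Z95), rel=1e-12)

    def test_published_scale_pump_attendant(self):
        # mu = ln 0.41, sigma = ln 3.41 -> P95 about 3.08 mg/m3
        _, _, p95 = derive_quantities(math.log(0.41), math.log(3.41))
        assert p95 == pytest.approx(0.41 * 3.41**Z95, rel=1e-12)
        assert p95 == pytest.approx(3.08, abs=0.02)


class TestCategoryProbabilities:
    def test_all_draws_above_oel(self):
        rep = category_probabilities(np.full(100, 5.0), CategoryScheme(oel=2.0))
        assert rep.probabilities == (0.0, 0.0, 0.0, 1.0)

    def test_one_draw_per_category(self):
        rep = category_probabilities(np.array([0.1, 0.5, 1.5, 2.5]), CategoryScheme(oel=2.0))
        assert rep.probabilities == (0.25, 0.25, 0.25, 0.25)

    def test_boundary_belongs_to_upper_category(self):
        rep = category_probabilities(np.array([0.2]), CategoryScheme(oel=2.0))
        assert rep.probabilities == (0.0, 1.0, 0.0, 0.0)
        rep = category_probabilities(np.array([2.0]), CategoryScheme(oel=2.0))
        assert rep.probabilities[3] == 1.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        draws=st.lists(st.floats(1e-3, 50), min_size=1, max_size=200),
        oel=st.floats(0.5, 10),
    )
    def test_probabilities_sum_to_one(self, draws, oel):
        rep = category_probabilities(np.array(draws), CategoryScheme(oel=oel))
        assert sum(rep.probabilities) == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance_with_oel(self, rng):
        """Scaling draws and OEL jointly leaves the report unchanged."""
        draws = rng.lognormal(0.5, 0.8, 500)
        a = category_probabilities(draws, CategoryScheme(oel=2.0))
        b = category_probabilities(7.3 * draws, CategoryScheme(oel=7.3 * 2.0))
        assert a.probabilities == b.probabilities


class TestGelmanRubin:
    def test_same_distribution_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 2000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.05)

    def test_constant_chains_at_different_values_diverges(self):
        chains = np.vstack([np.zeros(100), np.ones(100)])
        assert gelman_rubin(chains) == math.inf

    def test_identical_chains_below_one_by_finite_sample_factor(self, rng):
        one = rng.standard_normal(500)
        chains = np.vstack([one, one, one])
        # B = 0, so R-hat = sqrt((n-1)/n) exactly
        assert gelman_rubin(chains) == pytest.approx(math.sqrt(499 / 500), rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestSummarizePosterior:
    def _draws(self, flat):
        from expobayes.bayes_compliance import PosteriorDraws

        arr = np.log(np.asarray(flat, float)).reshape(2, -1)
        return PosteriorDraws(
            mu=arr, sigma=np.full_like(arr, 1e-9),
            space=ParameterSpace.unrestricted(), settings=FAST,
        )

    def test_constant_draws(self):
        d = self._draws(np.full(1000, 3.0))
        s = summarize_posterior(d)
        assert s.gm.median == pytest.approx(3.0)
        assert (s.gm.lo, s.gm.hi) == (pytest.approx(3.0), pytest.approx(3.0))

    def test_percentile_rule_linear_interpolation(self):
        d = self._draws(np.exp(np.arange(1.0, 1001.0) / 100))
        s = summarize_posterior(d)
        # gm draws are 1..1000 (scaled); check on the log scale via exp
        assert np.log(s.gm.median) * 100 == pytest.approx(500.5, abs=0.01)
        assert np.log(s.gm.lo) * 100 == pytest.approx(25.975, abs=0.01)
        assert np.log(s.gm.hi) * 100 == pytest.approx(975.025, abs=0.01)

    def test_few_draws_warns(self):
        d = self._draws(np.full(60, 2.0))
        with pytest.warns(UserWarning, match="100"):
            summarize_posterior(d)


def _matched_data(n, gm, gsd, seed=5):
    from expobayes.synthetic_data import GeneratorSpec, generate_matched_lognormal

    recs = generate_matched_lognormal(GeneratorSpec("x", n, gm, gsd, seed=seed))
    return log_sufficient_stats([r.twa8h for r in recs])


class TestGibbsSampler:
    def test_prior_dominance_limit(self):
        """A near-degenerate informative prior pins mu at the prior mean."""
        data = _matched_data(10, 1.0, 2.0)
        prior = PriorSpec("informative", prior_mean=0.7, prior_variance=1e-4, prior_n=1e5)
        draws = gibbs_sample(data, prior, ParameterSpace.unrestricted(), FAST)
        assert np.mean(draws.mu) == pytest.approx(0.7, abs=0.01)

    def test_truncation_containment(self):
        data = _matched_data(20, 1.0, 3.0)
        space = ParameterSpace(gm_lower=0.5, gm_upper=1.1, gsd_lower=1.5, gsd_upper=2.5)
        draws = gibbs_sample(data, PriorSpec("noninformative"), space, FAST)
        assert draws.gm.min() >= 0.5 and draws.gm.max() <= 1.1
        assert draws.gsd.min() >= 1.5 and draws.gsd.max() <= 2.5

    def test_sufficiency_bit_identical_posteriors(self):
        """Different datasets sharing (n, mean_log, sd_log) exactly give
        bit-identical posterior draws under the same seed.

        The two log-value multisets {0,0,1,3} and {-1,1,2,2} both have mean
        1 and sum of squared deviations 6, exactly in floating point."""
        a = log_sufficient_stats(np.exp([0.0, 0.0, 1.0, 3.0]))
        b = log_sufficient_stats(np.exp([-1.0, 1.0, 2.0, 2.0]))
        assert (a.n, a.mean_log, a.sd_log, a.sum_sq) == (b.n, b.mean_log, b.sd_log, b.sum_sq)
        space = ParameterSpace.default_box(math.e)
        da = gibbs_sample(a, PriorSpec("noninformative"), space, FAST)
        db = gibbs_sample(b, PriorSpec("noninformative"), space, FAST)
        assert np.array_equal(da.mu, db.mu)
        assert np.array_equal(da.sigma, db.sigma)

    def test_empty_truncation_region_is_diagnosed(self):
        data = _matched_data(50, 1.0, 2.0)
        space = ParameterSpace(gm_lower=500.0, gm_upper=600.0, gsd_lower=1.01, gsd_upper=1.02)
        with pytest.raises(TruncationError):
            gibbs_sample(data, PriorSpec("noninformative"), space, FAST)

    @pytest.mark.parametrize("kind", ["noninformative", "informative"])
    def test_small_n_moments_match_quadrature_oracle(self, kind):
        """Posterior means of mu and sigma agree with deterministic 2-D
        quadrature of the truncated posterior within 3 Monte-Carlo SEs."""
        data = _matched_data(10, 0.8, 2.8)
        if kind == "informative":
            prior = PriorSpec(kind, prior_mean=0.0, prior_variance=1.0, prior_n=5)
        else:
            prior = PriorSpec(kind)
        space = ParameterSpace.default_box(0.8)
        settings = MCMCSettings(chains=4, iterations=12_000, burn_in=2_000, seed=17)
        draws = gibbs_sample(data, prior, space, settings)
        e_mu, e_sig = oracles.grid_posterior_moments(data, prior, space)
        for got, want, chains in (
            (float(np.mean(draws.mu)), e_mu, draws.mu),
            (float(np.mean(draws.sigma)), e_sig, draws.sigma),
        ):
            se = oracles.mc_se(chains)
            assert abs(got - want) < 3 * max(se, 1e-6)

    def test_truncation_monotonicity_of_category4(self):
        """Enlarging the box weakly raises the exceedance probability."""
        scheme = CategoryScheme(oel=2.0)
        for gm, gsd, n in ((0.41, 3.41, 18), (1.08, 2.62, 46)):
            data = _matched_data(n, gm, gsd)
            tight = ParameterSpace.just_above(gm, gsd)
            wide = ParameterSpace.unrestricted()
            settings = MCMCSettings(chains=2, iterations=6000, burn_in=1000, seed=23)
            p_tight = category_probabilities(
                gibbs_sample(data, PriorSpec("noninformative"), tight, settings).flat("p95"),
                scheme,
            ).probabilities[3]
            p_wide = category_probabilities(
                gibbs_sample(data, PriorSpec("noninformative"), wide, settings).flat("p95"),
                scheme,
            ).probabilities[3]
            assert p_wide >= p_tight - 0.01

    def test_wide_box_posterior_median_gm_matches_sample_gm(self):
        data = _matched_data(116, 1.28, 3.30)
        draws = gibbs_sample(
            data, PriorSpec("noninformative"), ParameterSpace.default_box(1.28), FAST
        )
        s = summarize_posterior(draws)
        assert s.gm.median == pytest.approx(1.28, abs=0.03)
        rep = convergence_report(draws)
        assert rep.passed


class TestParameterSpace:
    def test_impossible_gsd_lower_bound_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            space = ParameterSpace(gm_lower=1e-5, gm_upper=10, gsd_lower=1e-5, gsd_upper=5)
        assert space.gsd_lower == 1.0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace(gm_lower=2.0, gm_upper=1.0, gsd_lower=1.1, gsd_upper=5.0)


class TestParameterRecovery:
    def test_cri_coverage_near_nominal(self):
        """95% CrIs for GM and GSD cover the generating values at close to
        the nominal rate across 200 random-mode replicates."""
        from expobayes.synthetic_data import GeneratorSpec, generate_matched_lognormal

        true_gm, true_gsd, n = 0.9, 2.5, 30
        space = ParameterSpace.default_box(true_gm)
        hits_gm = hits_gsd = 0
        reps = 200
        for i in range(reps):
            recs = generate_matched_lognormal(
                GeneratorSpec("x", n, true_gm, true_gsd, seed=1000 + i, match_mode="random")
            )
            data = log_sufficient_stats([r.twa8h for r in recs])
            settings = MCMCSettings(chains=2, iterations=1500, burn_in=300, seed=i)
            draws = gibbs_sample(data, PriorSpec("noninformative"), space, settings)
            s = summarize_posterior(draws)
            hits_gm += s.gm.lo <= true_gm <= s.gm.hi
            hits_gsd += s.gsd.lo <= true_gsd <= s.gsd.hi
        assert abs(hits_gm / reps - 0.95) <= 0.05
        assert abs(hits_gsd / reps - 0.95) <= 0.05
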