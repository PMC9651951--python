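"""Analytic checks on the shared probability primitives."""

import numpy as np
import pytest
from scipy import integrate, stats

from timecells.distributions import (
    bounded_powerlaw_cdf,
    bounded_powerlaw_logpdf,
    bounded_powerlaw_norm,
    bounded_powerlaw_ppf,
    lognormal_field_logpdf,
    lognormal_sd,
    population_logpdf,
    sample_bounded_powerlaw,
    trial_mixture_logpdf,
)


class TestBoundedPowerlaw:
    def test_cdf_endpoints(self):
        assert bounded_powerlaw_cdf(0.35, 1.0, 0.35, 7.2) == pytest.approx(0.0)
        assert bounded_powerlaw_cdf(7.2, 1.0, 0.35, 7.2) == pytest.approx(1.0)

    def test_cdf_hand_integration(self):
        # integral of tau^-2 from 1 to 2 over integral from 1 to 4
        assert bounded_powerlaw_cdf(2.0, 2.0, 1.0, 4.0) == pytest.approx(2.0 / 3.0)

    def test_alpha_one_limit_continuity(self):
        x = np.linspace(1.0, np.e, 11)
        near = bounded_powerlaw_cdf(x, 1.0 - 1e-9, 1.0, np.e)
        exact = bounded_powerlaw_cdf(x, 1.0, 1.0, np.e)
        assert np.max(np.abs(near - exact)) < 1e-6

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0, 1.0 + 5e-5, 2.0, 3.5])
    @pytest.mark.parametrize("lo,hi", [(0.35, 7.2), (1.0, 4.0), (0.1, 8.0)])
    def test_cdf_matches_quadrature(self, alpha, lo, hi):
        dens = lambda t: np.exp(bounded_powerlaw_logpdf(t, alpha, lo, hi))  # noqa: E731
        for x in np.linspace(lo, hi, 7):
            num, _ = integrate.quad(dens, lo, x)
            assert abs(num - bounded_powerlaw_cdf(x, alpha, lo, hi)) < 1e-8

    def test_normalizer_hand_value(self):
        # alpha=2 on [1, 4]: C = (4^-1 - 1^-1)/(-1) = 0.75; density(2) = 1/3
        assert bounded_powerlaw_norm(2.0, 1.0, 4.0) == pytest.approx(0.75)
        assert np.exp(bounded_powerlaw_logpdf(2.0, 2.0, 1.0, 4.0)) == pytest.approx(1 / 3)

    def test_alpha_one_unit_normalizer(self):
        # alpha=1 on [1, e]: C = 1 and density at tau=1 is 1
        assert bounded_powerlaw_norm(1.0, 1.0, np.e) == pytest.approx(1.0)
        assert np.exp(bounded_powerlaw_logpdf(1.0, 1.0, 1.0, np.e)) == pytest.approx(1.0)

    def test_alpha_zero_is_uniform(self):
        x = np.linspace(0.35, 7.2, 9)
        dens = np.exp(bounded_powerlaw_logpdf(x, 0.0, 0.35, 7.2))
        assert np.allclose(dens, 1.0 / (7.2 - 0.35))

    def test_logpdf_outside_support(self):
        assert bounded_powerlaw_logpdf(0.2, 1.0, 0.35, 7.2) == -np.inf
        assert bounded_powerlaw_logpdf(8.0, 1.0, 0.35, 7.2) == -np.inf

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            bounded_powerlaw_cdf(1.0, 1.0, 0.0, 7.2)
        with pytest.raises(ValueError):
            bounded_powerlaw_cdf(10.0, 1.0, 0.35, 7.2)

    def test_ppf_endpoints_and_roundtrip(self):
        assert bounded_powerlaw_ppf(0.0, 1.3, 0.35, 7.2) == pytest.approx(0.35)
        assert bounded_powerlaw_ppf(1.0, 1.3, 0.35, 7.2) == pytest.approx(7.2)
        u = np.linspace(0.01, 0.99, 13)
        x = bounded_powerlaw_ppf(u, 1.7, 0.35, 7.2)
        assert np.allclose(bounded_powerlaw_cdf(x, 1.7, 0.35, 7.2), u)


class TestSampler:
    def test_alpha_zero_uniform_mean(self):
        x = sample_bounded_powerlaw(0.0, 0.35, 7.2, 100_000, seed=1)
        assert x.mean() == pytest.approx((0.35 + 7.2) / 2, abs=0.05)

    def test_alpha_one_median_is_e(self):
        # CDF(e) = ln(e)/ln(e^2) = 1/2 on [1, e^2]
        x = sample_bounded_powerlaw(1.0, 1.0, np.e**2, 100_000, seed=2)
        assert np.median(x) == pytest.approx(np.e, rel=0.02)

    @pytest.mark.parametrize("alpha,lo,hi", [
        (0.0, 0.35, 7.2), (0.5, 0.35, 7.2), (1.0, 0.35, 7.2),
        (1.0, 1.0, 4.0), (2.0, 0.5, 8.0),
    ])
    def test_ks_agreement_with_cdf(self, alpha, lo, hi):
        """Draws match the analytic CDF (KS p > 0.01 in >= 9/10 seeds)."""
        ok = 0
        for seed in range(10):
            x = sample_bounded_powerlaw(alpha, lo, hi, 10_000, seed=seed)
            p = stats.kstest(x, lambda v: bounded_powerlaw_cdf(v, alpha, lo, hi)).pvalue
            ok += p > 0.01
        assert ok >= 9

    def test_bounds_respected_and_errors(self):
        x = sample_bounded_powerlaw(1.5, 0.35, 7.2, 1000, seed=0)
        assert x.min() >= 0.35 and x.max() <= 7.2
        with pytest.raises(ValueError):
            sample_bounded_powerlaw(1.0, 0.0, 7.2, 10, seed=0)


class TestTrialMixture:
    def test_background_only(self):
        assert trial_mixture_logpdf(3.3, 0.0, 4.0, 0.5, 8.0) == pytest.approx(np.log(0.125))

    def test_pure_field_at_mode(self):
        val = trial_mixture_logpdf(4.0, 1.0, 4.0, 0.5, 8.0)
        assert val == pytest.approx(-np.log(0.5 * np.sqrt(2 * np.pi)))

    def test_hand_value(self):
        # 0.5 * N(4|4,1) + 0.5/8 = 0.5*0.398942 + 0.0625 = 0.261971
        val = trial_mixture_logpdf(4.0, 0.5, 4.0, 1.0, 8.0)
        assert val == pytest.approx(np.log(0.261971), abs=1e-5)

    def test_nesting_exact_at_extremes(self):
        t = np.linspace(0, 8, 17)
        assert np.allclose(trial_mixture_logpdf(t, 0.0, 4.0, 0.5, 8.0),
                           np.log(1 / 8))
        assert np.allclose(trial_mixture_logpdf(t, 1.0, 4.0, 0.5, 8.0),
                           stats.norm.logpdf(t, 4.0, 0.5))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            trial_mixture_logpdf(9.0, 0.5, 4.0, 0.5, 8.0)

    def test_field_term_integrates_to_one(self):
        # untruncated field: a1 * N over the real line plus the uniform
        # mass over [0, L] sums to 1 for any a1
        for a1 in (0.0, 0.3, 1.0):
            field, _ = integrate.quad(
                lambda t: a1 * stats.norm.pdf(t, 4.0, 0.5), -np.inf, np.inf)
            assert field + (1 - a1) == pytest.approx(1.0, abs=1e-9)


class TestLognormalField:
    def test_background_only(self):
        assert lognormal_field_logpdf(2.0, 0.0, 0.0, 1.0, 8.0) == pytest.approx(np.log(1 / 8))

    def test_density_at_median(self):
        # mu=0, sigma=1, t=1: pdf = 1/sqrt(2 pi)
        val = lognormal_field_logpdf(1.0, 1.0, 0.0, 1.0, 8.0)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_sd_closed_form_vs_monte_carlo(self):
        assert lognormal_sd(0.0, 1.0) == pytest.approx(np.sqrt((np.e - 1) * np.e))
        draws = np.random.default_rng(3).lognormal(0.0, 1.0, 1_000_000)
        assert lognormal_sd(0.0, 1.0) == pytest.approx(draws.std(), rel=0.01)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            lognormal_field_logpdf(0.0, 0.5, 0.0, 1.0, 8.0)


class TestPopulationLaws:
    def test_weibull_k1_equals_exponential(self):
        tau = np.array([0.5, 1.0, 2.7, 6.0])
        w = population_logpdf(tau, "weibull_pop", {"k": 1.0, "lam": 2.0})
        e = population_logpdf(tau, "exponential_pop", {"beta": 0.5})
        assert np.allclose(w, e)

    def test_exponential_at_origin(self):
        # unbounded support: density -> beta as tau -> 0
        val = population_logpdf(1e-12, "exponential_pop", {"beta": 1.0})
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_weibull_closed_form(self):
        val = population_logpdf(1.0, "weibull_pop", {"k": 2.0, "lam": 1.0})
        assert np.exp(val) == pytest.approx(2.0 * np.exp(-1.0))

    @pytest.mark.parametrize("variant,params", [
        ("exponential_pop", {"beta": 0.4}),
        ("exponential_pop", {"beta": 2.0}),
        ("weibull_pop", {"k": 0.7, "lam": 2.0}),
        ("weibull_pop", {"k": 1.8, "lam": 3.0}),
    ])
    def test_truncated_density_normalizes(self, variant, params):
        dens = lambda t: np.exp(population_logpdf(t, variant, params, 0.35, 7.2))  # noqa: E731
        total, _ = integrate.quad(dens, 0.35, 7.2)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            population_logpdf(-1.0, "exponential_pop", {"beta": 1.0})
        with pytest.raises(ValueError):
            population_logpdf(1.0, "bogus", {})
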