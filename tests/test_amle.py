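"""Closed-form AMLE: coefficients, estimators, likelihood, numeric oracle."""

import numpy as np
import pytest

from iwamle import (
    CensoredSample,
    CensoringScheme,
    EVParams,
    FitError,
    censored_loglik,
    estimate_mu,
    estimate_theta,
    ev_std_pdf,
    expansion_coefficients,
    fit_amle,
    fit_mle_numeric,
    simulate_censored,
    AlternativeSpec,
    DERIVATION_CONSISTENT,
    PAPER_LITERAL,
)
from conftest import random_scheme

TOY = CensoredSample(CensoringScheme(5, [1, 3, 5]), np.exp([-1.0, 0.0, 2.0]))
# 30-digit symbolic solve of the linearized 2x2 system and theta quadratic
TOY_MU = -0.215685885754539703548829002419
TOY_THETA = 0.905969241000480904967651901257
TOY_LOGLIK = -7.28163961516464006714902645221  # at (mu=0.3, theta=1.2)


class TestSchemeAndSample:
    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            CensoringScheme(5, [1, 1, 3])
        with pytest.raises(ValueError):
            CensoringScheme(5, [0, 2])
        with pytest.raises(ValueError):
            CensoringScheme(5, [2, 6])
        assert CensoringScheme.complete(4).is_complete
        assert not CensoringScheme(4, [1, 2, 4]).is_complete

    def test_sample_validation(self):
        scheme = CensoringScheme(5, [1, 3, 5])
        with pytest.raises(ValueError):
            CensoredSample(scheme, [1.0, 2.0])  # wrong length
        with pytest.raises(ValueError):
            CensoredSample(scheme, [1.0, -2.0, 3.0])  # nonpositive
        with pytest.raises(ValueError):
            CensoredSample(scheme, [2.0, 1.0, 3.0])  # decreasing
        # ties are allowed
        CensoredSample(scheme, [1.0, 1.0, 3.0])

    def test_restrict_picks_ranks(self):
        full = CensoredSample(CensoringScheme.complete(5), [1.0, 2.0, 3.0, 4.0, 5.0])
        sub = full.restrict(CensoringScheme(5, [2, 4]))
        np.testing.assert_array_equal(sub.x, [2.0, 4.0])


class TestExpansionCoefficients:
    def test_requires_two_ranks(self):
        with pytest.raises(ValueError):
            expansion_coefficients(CensoringScheme(10, [4]))

    def test_printed_identities(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = expansion_coefficients(random_scheme(rng))
            np.testing.assert_allclose(c.beta2, -c.gamma1, rtol=1e-14)
            np.testing.assert_allclose(c.alpha3, c.alpha1 - c.alpha2, rtol=1e-14)
            np.testing.assert_allclose(c.beta3, c.beta1 - c.beta2, rtol=1e-14)
            np.testing.assert_allclose(c.gamma3, c.gamma1 - c.gamma2, rtol=1e-14)

    def test_tangent_value_identities(self):
        """Each linearization reproduces its target function at the expansion point."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            c = expansion_coefficients(random_scheme(rng))
            f = ev_std_pdf(c.xi)
            qs, xs, fs = c.q[-1], c.xi[-1], f[-1]
            assert c.kappa1 + c.delta1 * xs == pytest.approx(fs / qs, abs=1e-10, rel=1e-10)
            assert c.kappa2 + c.delta2 * xs == pytest.approx(fs * xs / qs, abs=1e-10, rel=1e-10)
            dp = c.p[1:] - c.p[:-1]
            np.testing.assert_allclose(
                c.alpha1 + c.beta1 * c.xi[1:] + c.gamma1 * c.xi[:-1], f[1:] / dp, rtol=1e-10
            )
            np.testing.assert_allclose(
                c.alpha2 + c.beta2 * c.xi[1:] + c.gamma2 * c.xi[:-1], f[:-1] / dp, rtol=1e-10
            )

    def test_depends_only_on_scheme(self):
        scheme = CensoringScheme(12, [2, 5, 9, 12])
        c1 = expansion_coefficients(scheme)
        c2 = expansion_coefficients(CensoringScheme(12, [2, 5, 9, 12]))
        for name in ("xi", "K", "alpha1", "beta4", "gamma3"):
            np.testing.assert_array_equal(getattr(c1, name), getattr(c2, name))
        assert c1.kappa1 == c2.kappa1


class TestEstimators:
    def test_toy_sample_against_symbolic_oracle(self):
        coeffs = expansion_coefficients(TOY.scheme)
        mu, _ = estimate_mu(TOY, coeffs)
        assert mu == pytest.approx(TOY_MU, rel=1e-12)
        theta, B1, C1 = estimate_theta(TOY, coeffs, mu)
        assert theta == pytest.approx(TOY_THETA, rel=1e-12)

    def test_location_equivariance_exact(self):
        d = 1.7
        fit0 = fit_amle(TOY)
        shifted = CensoredSample(TOY.scheme, TOY.x * np.exp(d))
        fit1 = fit_amle(shifted)
        assert fit1.ev.mu == pytest.approx(fit0.ev.mu + d, rel=1e-12)
        assert fit1.ev.theta == pytest.approx(fit0.ev.theta, rel=1e-12)
        # on the original scale: multiplying x by c divides sigma by c
        assert fit1.iw.sigma == pytest.approx(fit0.iw.sigma / np.exp(d), rel=1e-12)

    def test_scale_equivariance_exact(self):
        c = 2.5
        fit0 = fit_amle(TOY)
        powered = CensoredSample(TOY.scheme, TOY.x**c)
        fit1 = fit_amle(powered)
        assert fit1.ev.mu == pytest.approx(c * fit0.ev.mu, rel=1e-12)
        assert fit1.ev.theta == pytest.approx(c * fit0.ev.theta, rel=1e-12)
        assert fit1.iw.lambda_ == pytest.approx(fit0.iw.lambda_ / c, rel=1e-12)

    def test_back_transform_is_exact(self):
        fit = fit_amle(TOY)
        assert fit.iw.sigma == np.exp(-fit.ev.mu)
        assert fit.iw.lambda_ == 1 / fit.ev.theta

    def test_complete_uses_same_formulas_as_censored_limit(self):
        # a complete scheme fitted directly equals the generic pipeline with
        # all tail/gap multipliers zero; spot check against the numeric MLE
        rng = np.random.default_rng(3)
        sample = simulate_censored(
            AlternativeSpec("inverse_weibull"), CensoringScheme.complete(100), rng
        )
        fit = fit_amle(sample)
        mle = fit_mle_numeric(sample, init=fit.ev)
        assert fit.ev.mu == pytest.approx(mle.mu, abs=0.05)
        assert fit.ev.theta == pytest.approx(mle.theta, abs=0.05)

    def test_variant_label_recorded(self):
        assert fit_amle(TOY).variant == DERIVATION_CONSISTENT
        assert fit_amle(TOY, variant=PAPER_LITERAL).variant == PAPER_LITERAL

    def test_paper_literal_variant_differs(self):
        a = fit_amle(TOY)
        b = fit_amle(TOY, variant=PAPER_LITERAL)
        assert a.iw.lambda_ != b.iw.lambda_

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            fit_amle(TOY, variant="bogus")

    def test_mismatched_coefficients_rejected(self):
        other = expansion_coefficients(CensoringScheme(6, [1, 3, 5]))
        with pytest.raises(ValueError):
            estimate_mu(TOY, other)


class TestWorkedExamples:
    """The four published fits, complete and censored, to six decimals."""

    def test_ball_bearings(self, ball_bearings_complete, ball_bearings_censored):
        fit = fit_amle(ball_bearings_complete)
        assert round(fit.iw.lambda_, 6) == 2.121929
        assert round(fit.iw.sigma, 6) == 81.450162
        fit = fit_amle(ball_bearings_censored)
        assert round(fit.iw.lambda_, 6) == 2.062999
        assert round(fit.iw.sigma, 6) == 80.986041

    def test_flood_levels(self, flood_complete, flood_censored):
        fit = fit_amle(flood_complete)
        assert round(fit.iw.lambda_, 6) == 4.335915
        assert round(fit.iw.sigma, 6) == 2.783092
        fit = fit_amle(flood_censored)
        assert round(fit.iw.lambda_, 6) == 4.132622
        assert round(fit.iw.sigma, 6) == 2.770161


class TestCensoredLoglik:
    def test_complete_sample_reduces_to_density_sum(self):
        rng = np.random.default_rng(4)
        y = np.sort(rng.gumbel(size=8))
        sample = CensoredSample(CensoringScheme.complete(8), np.exp(y))
        params = EVParams(mu=0.2, theta=1.3)
        z = (y - params.mu) / params.theta
        expected = np.sum(np.log(ev_std_pdf(z))) - 8 * np.log(params.theta)
        assert censored_loglik(sample, params) == pytest.approx(expected, rel=1e-12)

    def test_toy_sample_against_symbolic_oracle(self):
        assert censored_loglik(TOY, EVParams(0.3, 1.2)) == pytest.approx(
            TOY_LOGLIK, rel=1e-12
        )

    def test_finite_for_increasing_data_any_theta(self):
        for theta in (0.05, 1.0, 50.0):
            assert np.isfinite(censored_loglik(TOY, EVParams(0.0, theta)))

    def test_degenerate_parameters_give_minus_inf(self):
        tied = CensoredSample(CensoringScheme(5, [1, 3, 5]), [1.0, 1.0, 1.0])
        # gap term F(z_j) - F(z_{j-1}) collapses for tied values
        assert censored_loglik(tied, EVParams(0.0, 1.0)) == float("-inf")


class TestNumericMLE:
    def test_gradient_vanishes_at_optimum(self):
        rng = np.random.default_rng(5)
        sample = simulate_censored(
            AlternativeSpec("inverse_weibull"), CensoringScheme(40, list(range(3, 35))), rng
        )
        opt = fit_mle_numeric(sample)
        h = 1e-5
        gmu = (
            censored_loglik(sample, EVParams(opt.mu + h, opt.theta))
            - censored_loglik(sample, EVParams(opt.mu - h, opt.theta))
        ) / (2 * h)
        gth = (
            censored_loglik(sample, EVParams(opt.mu, opt.theta + h))
            - censored_loglik(sample, EVParams(opt.mu, opt.theta - h))
        ) / (2 * h)
        assert abs(gmu) < 1e-3
        assert abs(gth) < 1e-3

    def test_close_to_amle_on_simulated_data(self):
        spec = AlternativeSpec("inverse_weibull", {"sigma": 1.0, "lambda_": 2.0})
        scheme = CensoringScheme.complete(100)
        coeffs = expansion_coefficients(scheme)
        close = 0
        reps = 50
        for r in range(reps):
            sample = simulate_censored(spec, scheme, np.random.default_rng([17, r]))
            amle = fit_amle(sample, coeffs=coeffs)
            mle = fit_mle_numeric(sample, init=amle.ev)
            if abs(amle.ev.mu - mle.mu) < 0.1 and abs(amle.ev.theta - mle.theta) < 0.1:
                close += 1
        assert close >= 0.9 * reps

    def test_gumbel_scale_one_case_matches_independent_root_find(self):
        """Complete case with lambda=1: compare against the standard Gumbel
        MLE obtained by solving the one-dimensional profile score."""
        from scipy.optimize import brentq

        rng = np.random.default_rng(6)
        y = np.sort(rng.gumbel(loc=0.5, scale=1.0, size=60))
        sample = CensoredSample(CensoringScheme.complete(60), np.exp(y))
        opt = fit_mle_numeric(sample)

        def profile_score(theta):
            wbar = np.sum(y * np.exp(-y / theta)) / np.sum(np.exp(-y / theta))
            return theta - np.mean(y) + wbar

        theta_star = brentq(profile_score, 0.1, 5.0, xtol=1e-12)
        mu_star = -theta_star * np.log(np.mean(np.exp(-y / theta_star)))
        assert opt.theta == pytest.approx(theta_star, abs=1e-5)
        assert opt.mu == pytest.approx(mu_star, abs=1e-5)


class TestFailureModes:
    def test_fit_error_carries_diagnostics(self):
        # two nearly identical points under heavy censoring can push the
        # quadratic root nonpositive; construct a genuinely degenerate case
        with pytest.raises((FitError, ValueError)):
            sample = CensoredSample(CensoringScheme(50, [24, 25]), [1.0, 1.0])
            fit_amle(sample)
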