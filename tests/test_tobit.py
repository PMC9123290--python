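"""Censored-regression engine: likelihood, MLE, expectations, logistic."""

import numpy as np
import pytest
from scipy.stats import norm

import genderpaths as gp
from genderpaths.tobit import censored_mean


def _sim_tobit(n, beta, sigma, seed):
    rng = np.random.default_rng(seed)
    X = np.column_stack(
        [np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n).astype(float)]
    )
    y = np.maximum(0.0, X @ np.asarray(beta) + rng.normal(0, sigma, n))
    return X, y


class TestLoglik:
    def test_reduces_to_gaussian_when_uncensored(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        beta = np.array([10.0, 1.0])
        y = X @ beta + rng.normal(0, 2.0, 20)
        y = np.maximum(y, 0.5)  # keep everything above the limit
        got = gp.tobit_loglik(beta, 2.0, X, y)
        want = float(np.sum(norm.logpdf(y, loc=X @ beta, scale=2.0)))
        assert got == pytest.approx(want, rel=1e-12)

    def test_single_censored_row_at_zero_mean(self):
        X = np.array([[1.0]])
        assert gp.tobit_loglik([0.0], 1.0, X, np.array([0.0])) == pytest.approx(
            np.log(0.5)
        )

    def test_five_row_fixture_matches_term_by_term_oracle(self):
        """Hand-tabulated design; oracle sums the density/CDF terms
        independently of the implementation."""
        X = np.array([[1.0, 0.5], [1.0, -1.0], [1.0, 2.0], [1.0, 0.0], [1.0, 1.5]])
        y = np.array([3.0, 0.0, 6.5, 0.0, 2.0])
        beta = np.array([1.0, 2.0])
        sigma = 2.5
        xb = X @ beta
        want = 0.0
        for i in range(5):
            if y[i] > 0:
                want += norm.logpdf((y[i] - xb[i]) / sigma) - np.log(sigma)
            else:
                want += norm.logcdf(-xb[i] / sigma)
        assert gp.tobit_loglik(beta, sigma, X, y) == pytest.approx(want, rel=1e-12)

    def test_rejects_nonfinite_design(self):
        with pytest.raises(gp.ValidationError):
            gp.tobit_loglik([0.0], 1.0, np.array([[np.inf]]), np.array([1.0]))


class TestFitTobit:
    def test_uncensored_limit_equals_gaussian_mle(self, rng):
        """With no censoring the tobit MLE is OLS beta and sigma^2=RSS/n."""
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([30.0, 2.0]) + rng.normal(0, 1.5, n)
        assert (y > 0).all()
        fit = gp.fit_tobit(X, y)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma_mle = float(np.sqrt(np.mean((y - X @ beta_ols) ** 2)))
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)
        assert fit.sigma == pytest.approx(sigma_mle, abs=1e-6)
        assert fit.n_censored == 0

    def test_matches_r_survreg_on_frozen_fixture(self):
        """Independent oracle: R survival::survreg (gaussian, left-censored)
        fitted once on this exact deterministic dataset; its estimates are
        frozen below."""
        rng = np.random.default_rng(20240915)
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, size=n).astype(float)
        X = np.column_stack([np.ones(n), x1, x2])
        y = np.maximum(0.0, X @ np.array([3.0, 1.5, -1.0]) + rng.normal(0, 4.0, n))
        fit = gp.fit_tobit(X, y)
        # survreg: coefficients, SEs, Log(scale) SE, scale, loglik
        np.testing.assert_allclose(
            fit.beta, [2.7228521846, 1.6637325055, -1.9610441807], atol=1e-6
        )
        np.testing.assert_allclose(
            fit.se, [0.6365487168, 0.5204947236, 1.0135420870], atol=1e-5
        )
        assert fit.sigma == pytest.approx(4.16079647838, abs=1e-6)
        assert fit.se_log_sigma == pytest.approx(0.1042457041, abs=1e-5)
        assert fit.loglik == pytest.approx(-172.694115101, abs=1e-6)

    def test_all_zero_outcome_raises(self):
        X = np.ones((10, 1))
        with pytest.raises(gp.EstimationError, match="no uncensored"):
            gp.fit_tobit(X, np.zeros(10))

    def test_loglik_never_below_start_and_monotone_path(self):
        X, y = _sim_tobit(500, [2.0, 1.5, -1.0], 3.0, seed=5)
        fit = gp.fit_tobit(X, y, track_path=True)
        assert fit.loglik >= fit.loglik_start
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-7).all()

    def test_rescaling_equivariance(self):
        """Multiplying a predictor by c divides its beta and SE by c."""
        X, y = _sim_tobit(600, [2.0, 1.5, -1.0], 3.0, seed=8)
        fit1 = gp.fit_tobit(X, y)
        c = 10.0
        X2 = X.copy()
        X2[:, 1] *= c
        fit2 = gp.fit_tobit(X2, y)
        np.testing.assert_allclose(fit2.beta[1] * c, fit1.beta[1], rtol=1e-8, atol=1e-8)
        np.testing.assert_allclose(fit2.se[1] * c, fit1.se[1], rtol=1e-6)
        np.testing.assert_allclose(fit2.beta[[0, 2]], fit1.beta[[0, 2]], atol=1e-7)
        assert fit2.sigma == pytest.approx(fit1.sigma, abs=1e-8)


class TestExpectedOutcome:
    def test_closed_form_at_zero_linear_predictor(self):
        assert censored_mean(0.0, 1.0) == pytest.approx(norm.pdf(0.0))

    def test_censoring_vanishes_for_large_mean(self):
        assert censored_mean(50.0, 1.0) == pytest.approx(50.0, abs=1e-10)

    def test_matches_monte_carlo(self, rng):
        draws = np.maximum(0.0, rng.normal(2.0, 2.0, size=1_000_000))
        mc_se = draws.std() / 1000.0
        assert censored_mean(2.0, 2.0) == pytest.approx(draws.mean(), abs=3 * mc_se)

    def test_tobit_expected_uses_fit(self):
        X, y = _sim_tobit(800, [2.0, 1.5, -1.0], 3.0, seed=2)
        fit = gp.fit_tobit(X, y)
        ey = gp.tobit_expected(fit, X)
        assert (ey >= 0).all()
        assert ey.mean() == pytest.approx(y.mean(), rel=0.1)


class TestLogistic:
    def test_two_by_two_matches_odds_ratio(self):
        """Saturated 2x2 logistic slope equals the ad/bc odds ratio."""
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [20, 10, 10, 20])
        yv = np.repeat([1.0, 0.0, 1.0, 0.0], [20, 10, 10, 20])
        fit = gp.fit_logistic(np.column_stack([np.ones(60), x]), yv)
        assert np.exp(fit.coef[1]) == pytest.approx(4.0, abs=1e-6)

    def test_null_slope_ci_coverage(self):
        """Independent outcome: Wald CI for the slope covers 0 at roughly
        the nominal rate over 200 seeded replicates."""
        cover = 0
        n_rep = 200
        master = np.random.default_rng(77)
        for _ in range(n_rep):
            x = master.normal(size=150)
            yv = master.binomial(1, 0.4, 150).astype(float)
            fit = gp.fit_logistic(np.column_stack([np.ones(150), x]), yv)
            lo, hi = fit.conf_int()[1]
            cover += lo <= 0.0 <= hi
        assert cover / n_rep >= 0.93

    def test_single_class_outcome_raises(self):
        X = np.ones((10, 1))
        with pytest.raises(gp.EstimationError, match="single class"):
            gp.fit_logistic(X, np.ones(10))

    def test_complete_separation_raises(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        yv = x.copy()
        with pytest.raises(gp.EstimationError, match="separation"):
            gp.fit_logistic(np.column_stack([np.ones(20), x]), yv)
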