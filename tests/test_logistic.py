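"""Retention-curve regression: IRLS correctness, oracles, bootstrap."""

import numpy as np
import pytest
from scipy.special import expit

from shepherdsim.logistic import (
    fit_retention_curve,
    identity_deviation,
    predict_retention,
)


def _simulate(beta0, beta1, n, m, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, n)
    mu = expit(beta0 + beta1 * x)
    y = rng.binomial(m, mu) / m
    return x, y


class TestFit:
    def test_flat_data_gives_zero_slope(self):
        x = np.linspace(0.1, 0.9, 9)
        y = np.full_like(x, 0.5)
        fit = fit_retention_curve(x, y, 100.0)
        assert fit.converged
        assert fit.beta1 == pytest.approx(0.0, abs=1e-6)
        assert predict_retention(fit, 0.3) == pytest.approx(0.5, abs=1e-6)

    def test_loglik_non_decreasing_over_iterations(self):
        x, y = _simulate(-1.0, 2.0, 50, 40, seed=5)
        fit = fit_retention_curve(x, y, 40.0)
        diffs = np.diff(fit.loglik_history)
        assert np.all(diffs >= -1e-9)

    def test_matches_brute_force_grid_search(self):
        """The IRLS optimum beats every point of a dense likelihood grid."""
        x, y = _simulate(0.5, -1.5, 30, 50, seed=2)
        m = np.full_like(x, 50.0)
        yc = np.clip(y, 1 / (2 * m), 1 - 1 / (2 * m))

        def loglik(b0, b1):
            mu = expit(b0 + b1 * x)
            return np.sum(m * (yc * np.log(mu) + (1 - yc) * np.log(1 - mu)))

        b0g = np.arange(-2.0, 2.0001, 0.02)
        b1g = np.arange(-4.0, 4.0001, 0.02)
        grid_ll = np.array([[loglik(b0, b1) for b1 in b1g] for b0 in b0g])
        i, j = np.unravel_index(np.argmax(grid_ll), grid_ll.shape)

        fit = fit_retention_curve(x, y, 50.0)
        assert fit.loglik >= grid_ll[i, j] - 1e-9
        assert fit.beta0 == pytest.approx(b0g[i], abs=0.02)
        assert fit.beta1 == pytest.approx(b1g[j], abs=0.02)

    def test_matches_statsmodels_glm(self):
        """Independent cross-check against a reference GLM implementation."""
        import statsmodels.api as sm

        x, y = _simulate(-0.8, 1.7, 80, 60, seed=9)
        m = np.full_like(x, 60.0)
        yc = np.clip(y, 1 / (2 * m), 1 - 1 / (2 * m))
        X = sm.add_constant(x)
        ref = sm.GLM(yc, X, family=sm.families.Binomial(), var_weights=m).fit()

        fit = fit_retention_curve(x, y, 60.0)
        assert fit.beta0 == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se_beta0 == pytest.approx(ref.bse[0], rel=1e-4)
        assert fit.se_beta1 == pytest.approx(ref.bse[1], rel=1e-4)

    def test_identical_x_rejected(self):
        with pytest.raises(ValueError):
            fit_retention_curve(np.full(5, 0.5), np.linspace(0.1, 0.9, 5))

    def test_boundary_proportions_are_clamped_not_fatal(self):
        x = np.array([0.1, 0.4, 0.6, 0.9])
        y = np.array([0.0, 0.2, 0.8, 1.0])
        fit = fit_retention_curve(x, y, 20.0)
        assert np.isfinite(fit.loglik)


class TestPredict:
    def test_closed_form_midpoint(self):
        x, y = _simulate(-1.0, 2.0, 200, 200, seed=1)
        fit = fit_retention_curve(x, y, 200.0)
        # At x = 0.5 the true curve passes through expit(-1 + 1) = 0.5.
        assert predict_retention(fit, 0.5) == pytest.approx(0.5, abs=0.03)

    def test_limits(self):
        from shepherdsim.logistic import LogisticFit

        fit = LogisticFit(0.0, 50.0, 0, 0, 0, True, 2, 1)
        assert predict_retention(fit, 1.0) > 0.999
        fit0 = LogisticFit(0.0, 0.0, 0, 0, 0, True, 2, 1)
        assert predict_retention(fit0, 0.77) == pytest.approx(0.5)


class TestIdentityDeviation:
    def test_flat_curve_deviation_quarter(self):
        x = np.linspace(0.1, 0.9, 20)
        y = np.full_like(x, 0.5)
        fit = fit_retention_curve(x, y, 100.0)
        dev = identity_deviation(fit, grid_size=1001, bootstrap_reps=10, seed=0)
        assert dev.mean_abs_deviation_from_identity == pytest.approx(0.25, abs=0.005)

    def test_bootstrap_reproducible(self, reference_cases):
        from shepherdsim.cases import effective_ratio

        pairs = [
            (effective_ratio(c.parent_ratio), effective_ratio(c.offspring_ratio))
            for c in reference_cases
        ]
        pairs = [(a, b) for a, b in pairs if a is not None]
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        fit = fit_retention_curve(x, y, 30.0)
        d1 = identity_deviation(fit, bootstrap_reps=200, seed=123)
        d2 = identity_deviation(fit, bootstrap_reps=200, seed=123)
        assert d1.bootstrap_ci == d2.bootstrap_ci
        # The fitted curve demonstrably departs from 1:1 transmission.
        assert d1.mean_abs_deviation_from_identity > 0
        assert d1.bootstrap_ci[0] > 0

    def test_invalid_arguments_rejected(self):
        x = np.linspace(0.1, 0.9, 10)
        fit = fit_retention_curve(x, x, 30.0)
        with pytest.raises(ValueError):
            identity_deviation(fit, grid_size=1)
        with pytest.raises(ValueError):
            identity_deviation(fit, bootstrap_reps=0)
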