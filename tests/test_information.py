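import numpy as np
import pandas as pd
import pytest

import fracinfo as fi
from fracinfo.exceptions import DifferentiationError
from fracinfo.models import MomentSet


def saturated_info_oracle(moments, pats):
    """Negative numeric Hessian of the saturated observed log-likelihood.

    The independent definition of the unstructured observed
    information, against which the analytic fast path is checked.
    """
    spec = fi.make_saturated_model(pats.p)
    theta0 = np.concatenate([moments.mu, fi.vech(moments.sigma)])
    return -fi.numeric_hessian(
        lambda th: fi.observed_loglik(spec, th, pats), theta0
    )


class TestNumericHessian:
    def test_quadratic_exactness(self):
        a = np.array([[2.0, 1.0], [1.0, 3.0]])
        hess = fi.numeric_hessian(lambda x: 0.5 * x @ a @ x, np.array([0.3, -0.7]))
        assert np.allclose(hess, a, atol=1e-6)

    def test_normal_loglik_curvature(self, rng):
        # curvature of the loglik in mu at the MLE is n / sigma^2
        x = rng.standard_normal(50)
        sig2 = x.var()

        def loglik(par):
            return -0.5 * np.sum((x - par[0]) ** 2) / par[1] - 25 * np.log(par[1])

        hess = fi.numeric_hessian(loglik, np.array([x.mean(), sig2]))
        assert -hess[0, 0] == pytest.approx(50 / sig2, rel=1e-4)

    def test_step_halving_stability(self):
        def f(x):
            return np.sin(x[0]) * np.exp(0.3 * x[1]) + x[0] ** 2 * x[1]

        x0 = np.array([0.4, -0.2])
        h1 = fi.numeric_hessian(f, x0)
        h2 = fi.numeric_hessian(f, x0, step_scale=5e-5)
        assert np.max(np.abs(h1 - h2)) / np.max(np.abs(h1)) < 1e-5

    def test_nonfinite_evaluation_raises(self):
        with np.errstate(invalid="ignore"), pytest.raises(DifferentiationError):
            fi.numeric_hessian(lambda x: np.log(x[0]), np.array([1e-9]))


class TestH1Information:
    def test_complete_data_blocks_at_mle(self, rng):
        vals = rng.standard_normal((80, 2)) @ np.array([[1.0, 0.0], [0.4, 0.9]])
        data = pd.DataFrame(vals, columns=["A", "B"])
        pats = fi.pattern_partition(data)
        mu_hat = vals.mean(axis=0)
        s_hat = (vals - mu_hat).T @ (vals - mu_hat) / 80
        info = fi.h1_observed_info(MomentSet(mu_hat, s_hat), pats)
        # mean block N * Sigma^{-1}; mean-cov cross block zero (d = 0)
        assert np.allclose(info[:2, :2], 80 * np.linalg.inv(s_hat), atol=1e-8)
        assert np.allclose(info[:2, 2:], 0.0, atol=1e-8)

    def test_univariate_closed_form(self, rng):
        x = rng.standard_normal(40)
        data = pd.DataFrame({"A": x})
        pats = fi.pattern_partition(data)
        sig2 = x.var()
        info = fi.h1_observed_info(MomentSet(np.array([x.mean()]), np.array([[sig2]])), pats)
        assert info[0, 0] == pytest.approx(40 / sig2)
        assert info[1, 1] == pytest.approx(40 / (2 * sig2**2))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_numeric_hessian_oracle(self, seed):
        """Normative contract: the analytic h1 information is the negative
        Hessian of the saturated observed log-likelihood, at arbitrary
        admissible moments and arbitrary missingness."""
        rng = np.random.default_rng(seed)
        p = rng.integers(2, 5)
        n = 40
        mat = rng.standard_normal((p, p))
        pop_sigma = mat @ mat.T + p * np.eye(p)
        data = rng.multivariate_normal(rng.standard_normal(p), pop_sigma, size=n)
        miss = rng.random((n, p)) < 0.3
        miss[miss.all(axis=1)] = False
        data[miss] = np.nan
        pats = fi.pattern_partition(pd.DataFrame(data))
        mat2 = rng.standard_normal((p, p))
        moments = MomentSet(
            rng.standard_normal(p), mat2 @ mat2.T + p * np.eye(p)
        )
        analytic = fi.h1_observed_info(moments, pats)
        oracle = saturated_info_oracle(moments, pats)
        scale = np.max(np.abs(analytic))
        assert np.max(np.abs(analytic - oracle)) <= 1e-5 * scale


class TestObservedInfo:
    def test_univariate_complete_closed_form(self, rng):
        x = rng.standard_normal(60)
        pats = fi.pattern_partition(pd.DataFrame({"A": x}))
        spec = fi.make_saturated_model(1)
        fit = fi.fit_fiml(spec, pats)
        info = fi.observed_info_hessian(spec, fit.theta.values, pats)
        sig2 = fit.theta.values[1]
        assert info.matrix[0, 0] == pytest.approx(60 / sig2, rel=1e-4)
        assert info.matrix[1, 1] == pytest.approx(60 / (2 * sig2**2), rel=1e-4)

    def test_regression_complete_matches_ols_ml_se(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n) * 0.9
        data = pd.DataFrame({"X": x, "Y": y})
        pats = fi.pattern_partition(data)
        spec = fi.make_regression_model()
        fit = fi.fit_fiml(spec, pats)
        info = fi.observed_info_hessian(spec, fit.theta.values, pats)
        cov = np.linalg.inv(info.matrix)
        est = dict(zip(fit.theta.names, fit.theta.values))
        # ML slope variance: psi / (n * s_xx)
        s_xx = x.var()
        assert cov[3, 3] == pytest.approx(est["psi"] / (n * s_xx), rel=1e-4)

    def test_analytic_equals_h1_for_saturated_spec(self, bivariate_incomplete):
        pats = fi.pattern_partition(bivariate_incomplete)
        spec = fi.make_saturated_model(2, ("X", "Y"))
        fit = fi.fit_fiml(spec, pats)
        info = fi.observed_info_analytic(spec, fit.theta.values, pats)
        direct = fi.h1_observed_info(fit.moments, pats)
        assert np.allclose(info.matrix, direct, atol=1e-8)


class TestCompleteInfo:
    def test_no_missing_data_complete_equals_observed(self, rng):
        data = pd.DataFrame(
            rng.standard_normal((150, 2)) + np.array([1.0, -0.5]),
            columns=["X", "Y"],
        )
        pats = fi.pattern_partition(data)
        spec = fi.make_regression_model()
        fit = fi.fit_fiml(spec, pats)
        for method, observed in (
            ("hessian", fi.observed_info_hessian(spec, fit.theta.values, pats)),
            (
                "analytic_structured",
                fi.observed_info_analytic(spec, fit.theta.values, pats),
            ),
        ):
            complete = fi.complete_info(spec, fit.theta.values, 150, method=method)
            assert np.allclose(
                complete.matrix, observed.matrix, rtol=1e-4, atol=1e-6
            )

    def test_univariate_pseudo_sample_closed_form(self):
        spec = fi.make_saturated_model(1)
        theta = np.array([0.0, 1.0])
        info = fi.complete_info(spec, theta, 100, method="analytic_structured")
        assert np.allclose(info.matrix, np.diag([100.0, 50.0]))

    def test_information_scales_linearly_in_n(self):
        spec = fi.make_saturated_model(2)
        theta = np.concatenate([[0.1, -0.2], fi.vech(np.array([[1.0, 0.3], [0.3, 2.0]]))])
        i1 = fi.complete_info(spec, theta, 500, method="analytic_structured")
        i2 = fi.complete_info(spec, theta, 1000, method="analytic_structured")
        assert np.allclose(i2.matrix, 2.0 * i1.matrix)

    def test_observed_variance_exceeds_complete_variance(self, bivariate_incomplete):
        """Information ordering: missing data cannot shrink sampling variance."""
        pats = fi.pattern_partition(bivariate_incomplete)
        spec = fi.make_regression_model()
        fit = fi.fit_fiml(spec, pats)
        j_y = fi.observed_info_hessian(spec, fit.theta.values, pats)
        j_x = fi.complete_info(spec, fit.theta.values, pats.n_total, method="hessian")
        var_y = np.diag(np.linalg.inv(j_y.matrix))
        var_x = np.diag(np.linalg.inv(j_x.matrix))
        assert np.all(var_y >= var_x - 1e-10)
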