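import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fracinfo as fi
from fracinfo.exceptions import ConfigurationError, InadmissibleMomentsError


class TestVech:
    def test_roundtrip(self, rng):
        mat = rng.standard_normal((5, 5))
        mat = mat + mat.T
        assert np.array_equal(fi.unvech(fi.vech(mat), 5), mat)

    def test_duplication_matrix_reconstructs_vec(self, rng):
        mat = rng.standard_normal((4, 4))
        mat = mat + mat.T
        d = fi.duplication_matrix(4)
        assert np.allclose(d @ fi.vech(mat), mat.flatten(order="F"))

    def test_ordering_is_column_major_lower(self):
        mat = np.array([[1.0, 2.0], [2.0, 3.0]])
        assert fi.vech(mat).tolist() == [1.0, 2.0, 3.0]


class TestRegressionModel:
    @pytest.mark.parametrize(
        "theta, mu_exp, sigma_exp",
        [
            # unit-variance population with slope 0.4: 0.4^2*1 + 0.84 = 1
            ((0, 1, 0, 0.4, 0.84), (0, 0), [[1, 0.4], [0.4, 1]]),
            # zero slope decouples the two variables
            ((0, 1, 0, 0, 1), (0, 0), [[1, 0], [0, 1]]),
            # hand-substituted: mu_Y = 1 + 0.5*2, sigma_12 = 0.5*4
            ((2, 4, 1, 0.5, 3), (2, 2), [[4, 2], [2, 4]]),
        ],
    )
    def test_implied_moments(self, theta, mu_exp, sigma_exp):
        spec = fi.make_regression_model()
        mom = fi.implied_moments(spec, np.asarray(theta, dtype=float))
        assert np.allclose(mom.mu, mu_exp)
        assert np.allclose(mom.sigma, sigma_exp)

    def test_five_free_parameters_saturated(self):
        spec = fi.make_regression_model()
        assert spec.q == 5
        assert spec.df == 0

    @given(beta=st.floats(-0.99, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_implied_correlation_equals_slope(self, beta):
        # with unit X variance and unit Y variance the correlation is beta
        spec = fi.make_regression_model()
        psi = 1.0 - beta**2 + 1e-9
        mom = fi.implied_moments(spec, np.array([0.0, 1.0, 0.0, beta, psi]))
        corr = mom.sigma[0, 1] / np.sqrt(mom.sigma[0, 0] * mom.sigma[1, 1])
        assert corr == pytest.approx(beta, abs=1e-6)


class TestTwoFactorModel:
    def test_parameter_count(self):
        spec = fi.make_two_factor_model()
        assert spec.p == 8
        assert spec.q == 25
        assert spec.df == 19

    def test_implied_covariance_structure(self):
        spec = fi.make_two_factor_model()
        lam, phi = 0.49, 0.4
        theta = self._theta(spec, lam, phi)
        mom = fi.implied_moments(spec, theta)
        i_x1, i_x3 = spec.var_names.index("X1"), spec.var_names.index("X3")
        i_y1 = spec.var_names.index("Y1")
        assert mom.sigma[i_x1, i_x3] == pytest.approx(lam**2)
        assert mom.sigma[i_x1, i_y1] == pytest.approx(lam * phi * lam)
        assert np.allclose(np.diag(mom.sigma), 1.0)

    def test_orthogonal_factors_block_diagonal(self):
        spec = fi.make_two_factor_model()
        mom = fi.implied_moments(spec, self._theta(spec, 0.49, 0.0))
        x_idx = [spec.var_names.index(f"X{i}") for i in range(1, 5)]
        y_idx = [spec.var_names.index(f"Y{i}") for i in range(1, 5)]
        assert np.allclose(mom.sigma[np.ix_(x_idx, y_idx)], 0.0)

    def test_std_lv_identification(self):
        spec = fi.make_two_factor_model()
        fixed = [p for p in spec.params if not p.free]
        assert {p.name for p in fixed} == {"psi[F1]", "psi[F2]"}
        assert all(p.fixed_value == 1.0 for p in fixed)

    @staticmethod
    def _theta(spec, lam, phi):
        values = []
        for par in spec.free_params:
            if par.role == "loading":
                values.append(lam)
            elif par.role == "factor_cov":
                values.append(phi)
            elif par.role == "error_var":
                values.append(1.0 - lam**2)
            else:
                values.append(0.0)
        return np.asarray(values)


class TestSaturatedModel:
    @pytest.mark.parametrize("p, q", [(1, 2), (2, 5), (8, 44)])
    def test_parameter_count(self, p, q):
        assert fi.make_saturated_model(p).q == q

    def test_rejects_nonpositive_p(self):
        with pytest.raises(ConfigurationError):
            fi.make_saturated_model(0)

    def test_moments_are_parameters(self, rng):
        spec = fi.make_saturated_model(3)
        mat = rng.standard_normal((3, 3))
        sigma = mat @ mat.T + np.eye(3)
        mu = rng.standard_normal(3)
        theta = np.concatenate([mu, fi.vech(sigma)])
        mom = fi.implied_moments(spec, theta)
        assert np.allclose(mom.mu, mu)
        assert np.allclose(mom.sigma, sigma)

    def test_inadmissible_sigma_raises_with_eigenvalue(self):
        spec = fi.make_saturated_model(2)
        theta = np.array([0.0, 0.0, 1.0, 2.0, 1.0])  # corr 2 -> indefinite
        with pytest.raises(InadmissibleMomentsError) as err:
            fi.implied_moments(spec, theta)
        assert err.value.min_eigenvalue < 0


class TestModelJacobian:
    def test_saturated_is_exact_identity(self):
        spec = fi.make_saturated_model(3)
        theta = np.concatenate([np.zeros(3), fi.vech(np.eye(3))])
        jac = fi.model_jacobian(spec, theta)
        assert np.array_equal(jac, np.eye(9))

    def test_regression_slope_derivative(self):
        # d sigma_12 / d beta = phi_X
        spec = fi.make_regression_model()
        theta = np.array([0.0, 1.0, 0.0, 0.4, 0.84])
        jac = fi.model_jacobian(spec, theta)
        row_sigma12 = 2 + 1  # means (2 rows) then vech: s11, s21, s22
        assert jac[row_sigma12, 3] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("maker", [fi.make_regression_model, fi.make_two_factor_model])
    def test_step_halving_agreement(self, maker):
        spec = maker()
        if spec.kind == "regression":
            theta = np.array([0.3, 1.2, -0.1, 0.4, 0.8])
        else:
            theta = fi.fiml.moments_to_start(
                spec, fi.implied_moments(spec, TestTwoFactorModel._theta(spec, 0.49, 0.4))
            )
        jac = fi.model_jacobian(spec, theta)
        # brute-force recomputation at half the step size
        half = np.empty_like(jac)
        for j in range(spec.q):
            h = 0.5e-5 * max(1.0, abs(theta[j]))
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            half[:, j] = (
                fi.implied_moments(spec, up).stacked()
                - fi.implied_moments(spec, dn).stacked()
            ) / (2 * h)
        assert np.max(np.abs(jac - half)) < 1e-6

    def test_wrong_length_theta_rejected(self):
        with pytest.raises(ConfigurationError):
            fi.model_jacobian(fi.make_regression_model(), np.zeros(4))


class TestModelConfig:
    def test_cfa_measurement_syntax(self):
        factors = fi.parse_cfa_syntax("visual =~ x1 + x2 + x3\nspeed =~ x7 + x8")
        assert factors == {"visual": ["x1", "x2", "x3"], "speed": ["x7", "x8"]}

    def test_config_roundtrip(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(
            "kind: cfa\nmodel: |\n  F1 =~ a + b + c\n  F2 =~ d + e + f\n"
        )
        spec = fi.model_from_config(cfg)
        assert spec.kind == "cfa"
        assert spec.p == 6
        # 6 loadings + 1 factor correlation + 6 error vars + 6 means
        assert spec.q == 19

    def test_double_assignment_rejected(self):
        with pytest.raises(ConfigurationError):
            fi.make_cfa_model({"F1": ["a", "b"], "F2": ["b", "c"]})

    def test_bad_syntax_rejected(self):
        with pytest.raises(ConfigurationError):
            fi.parse_cfa_syntax("F1 ~ a + b")
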