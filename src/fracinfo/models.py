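"""Mean-and-covariance structure models.

A model is a parametric map ``theta -> (mu(theta), Sigma(theta))`` for a
vector of p observed variables, with q free parameters.  Three families
are provided:

* ``saturated`` — the unstructured multivariate normal; the parameters
  are the moments themselves, ``theta = (mu, vech(Sigma))``.
* ``regression`` — the bivariate path model Y = alpha + beta*X + E with
  free exogenous mean/variance; five parameters, zero degrees of
  freedom (a saturated reparametrization).
* ``cfa`` — simple-structure confirmatory factor analysis with the
  latent variances fixed to 1 (std.lv identification) so that every
  loading is free; factor covariances, error variances and indicator
  means are free.

The stacked moment vector everywhere is ``(mu, vech(Sigma))`` with the
vech ordering of :mod:`fracinfo._linalg`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import min_eigval, unvech, vech, vech_indices
from .exceptions import ConfigurationError, InadmissibleMomentsError

ROLES = frozenset(
    {
        "mean",
        "loading",
        "factor_cov",
        "error_var",
        "regression_slope",
        "intercept",
        "variance",
        "covariance",
    }
)

#: parameter roles constrained to be strictly positive
POSITIVE_ROLES = frozenset({"error_var", "variance"})
#: parameter roles that are correlations under std.lv identification
CORRELATION_ROLES = frozenset({"factor_cov"})


@dataclass(frozen=True)
class Parameter:
    name: str
    role: str
    free: bool = True
    fixed_value: float | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown parameter role {self.role!r}")
        if not self.free and self.fixed_value is None:
            raise ConfigurationError(f"fixed parameter {self.name!r} needs a value")


@dataclass(frozen=True)
class ParameterVector:
    """A value for the free parameters of a model."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size != len(self.names):
            raise ConfigurationError("parameter values and names do not align")


@dataclass(frozen=True)
class MomentSet:
    """A mean vector and covariance matrix with its provenance."""

    mu: np.ndarray
    sigma: np.ndarray
    source: str = "implied"  # implied | saturated_em | sample

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))

    @property
    def p(self) -> int:
        return self.mu.size

    def stacked(self) -> np.ndarray:
        """The moment vector (mu, vech(Sigma))."""
        return np.concatenate([self.mu, vech(self.sigma)])


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of a mean-and-covariance model."""

    kind: str
    var_names: tuple[str, ...]
    params: tuple[Parameter, ...]
    factor_names: tuple[str, ...] = ()
    # simple structure: indicator i loads on factor loading_map[i]
    loading_map: tuple[int, ...] = ()
    identification: str = "std_lv"

    @property
    def p(self) -> int:
        return len(self.var_names)

    @property
    def n_moments(self) -> int:
        return self.p + self.p * (self.p + 1) // 2

    @property
    def free_params(self) -> tuple[Parameter, ...]:
        return tuple(par for par in self.params if par.free)

    @property
    def q(self) -> int:
        return len(self.free_params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(par.name for par in self.free_params)

    @property
    def param_roles(self) -> tuple[str, ...]:
        return tuple(par.role for par in self.free_params)

    @property
    def df(self) -> int:
        """Degrees of freedom: moments minus free parameters."""
        return self.n_moments - self.q

    def index_of(self, name: str) -> int:
        """Position of a free parameter by name."""
        try:
            return self.param_names.index(name)
        except ValueError:
            raise ConfigurationError(f"no free parameter named {name!r}") from None


# ---------------------------------------------------------------------------
# constructors


def make_saturated_model(p: int, var_names: tuple[str, ...] | None = None) -> ModelSpec:
    """Unstructured model: theta = (mu_1..mu_p, vech(Sigma))."""
    if p < 1:
        raise ConfigurationError(f"need p >= 1 observed variables, got {p}")
    if var_names is None:
        var_names = tuple(f"V{i + 1}" for i in range(p))
    if len(var_names) != p:
        raise ConfigurationError("var_names length does not match p")
    params = [Parameter(f"mu[{v}]", "mean") for v in var_names]
    r, c = vech_indices(p)
    for i, j in zip(r, c):
        role = "variance" if i == j else "covariance"
        params.append(Parameter(f"Sigma[{var_names[i]},{var_names[j]}]", role))
    return ModelSpec(kind="saturated", var_names=tuple(var_names), params=tuple(params))


def make_regression_model(var_names: tuple[str, str] = ("X", "Y")) -> ModelSpec:
    """Bivariate path model Y = alpha + beta*X + E.

    theta = (mu_X, phi_X, alpha, beta, psi): the mean and variance of X,
    the intercept, slope and residual variance of Y.  Saturated (df = 0),
    but with the slope as a bona-fide parameter with its own FMI.
    """
    x, y = var_names
    params = (
        Parameter(f"mu[{x}]", "mean"),
        Parameter(f"phi[{x}]", "variance"),
        Parameter("alpha", "intercept"),
        Parameter("beta", "regression_slope"),
        Parameter("psi", "error_var"),
    )
    return ModelSpec(kind="regression", var_names=(x, y), params=params)


def make_cfa_model(
    factors: dict[str, list[str]],
    var_names: tuple[str, ...] | None = None,
) -> ModelSpec:
    """Simple-structure CFA with std.lv identification.

    Each observed variable loads on exactly one factor; latent variances
    are fixed to 1, so all loadings, the factor covariances (here
    correlations), the error variances and the indicator means are free.

    Parameters
    ----------
    factors
        Mapping factor name -> list of indicator names.
    var_names
        Observed-variable order; defaults to the order of appearance.
    """
    if not factors:
        raise ConfigurationError("a CFA needs at least one factor")
    indicator_factor: dict[str, str] = {}
    for fac, inds in factors.items():
        if not inds:
            raise ConfigurationError(f"factor {fac!r} has no indicators")
        for v in inds:
            if v in indicator_factor:
                raise ConfigurationError(
                    f"indicator {v!r} assigned to more than one factor"
                )
            indicator_factor[v] = fac
    if var_names is None:
        var_names = tuple(indicator_factor)
    missing = set(indicator_factor) - set(var_names)
    if missing or len(var_names) != len(indicator_factor):
        raise ConfigurationError("var_names must list exactly the indicators")
    fnames = tuple(factors)
    fidx = {f: k for k, f in enumerate(fnames)}
    loading_map = tuple(fidx[indicator_factor[v]] for v in var_names)

    params: list[Parameter] = []
    for v in var_names:
        params.append(Parameter(f"lambda[{v}]", "loading"))
    k = len(fnames)
    for j in range(k):
        params.append(Parameter(f"psi[{fnames[j]}]", "variance", free=False, fixed_value=1.0))
        for i in range(j + 1, k):
            params.append(Parameter(f"phi[{fnames[i]},{fnames[j]}]", "factor_cov"))
    for v in var_names:
        params.append(Parameter(f"theta[{v}]", "error_var"))
    for v in var_names:
        params.append(Parameter(f"mu[{v}]", "mean"))
    return ModelSpec(
        kind="cfa",
        var_names=tuple(var_names),
        params=tuple(params),
        factor_names=fnames,
        loading_map=loading_map,
    )


def make_two_factor_model() -> ModelSpec:
    """Two correlated factors, four indicators each (X1..X4, Y1..Y4).

    25 free parameters: 8 loadings, 1 factor correlation, 8 error
    variances, 8 means; df = 19.
    """
    return make_cfa_model(
        {
            "F1": ["X1", "X2", "X3", "X4"],
            "F2": ["Y1", "Y2", "Y3", "Y4"],
        }
    )


# ---------------------------------------------------------------------------
# implied moments and derivatives


def _check_theta(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size != spec.q:
        raise ConfigurationError(
            f"theta has length {theta.size}, model has q={spec.q} free parameters"
        )
    return theta


def _cfa_matrices(spec: ModelSpec, theta: np.ndarray):
    p, k = spec.p, len(spec.factor_names)
    values = {par.name: par.fixed_value for par in spec.params if not par.free}
    values.update(dict(zip(spec.param_names, theta)))
    lam = np.zeros((p, k))
    for i, v in enumerate(spec.var_names):
        lam[i, spec.loading_map[i]] = values[f"lambda[{v}]"]
    phi = np.zeros((k, k))
    for j, fj in enumerate(spec.factor_names):
        phi[j, j] = values[f"psi[{fj}]"]
        for i in range(j + 1, k):
            fi = spec.factor_names[i]
            phi[i, j] = phi[j, i] = values[f"phi[{fi},{fj}]"]
    theta_d = np.array([values[f"theta[{v}]"] for v in spec.var_names])
    mu = np.array([values[f"mu[{v}]"] for v in spec.var_names])
    return mu, lam, phi, theta_d


def implied_moments(spec: ModelSpec, theta: np.ndarray) -> MomentSet:
    """Model-implied (mu(theta), Sigma(theta)).

    Raises
    ------
    InadmissibleMomentsError
        If the implied covariance matrix is not positive definite.
    """
    theta = _check_theta(spec, theta)
    p = spec.p
    if spec.kind == "saturated":
        mu = theta[:p]
        sigma = unvech(theta[p:], p)
    elif spec.kind == "regression":
        mu_x, phi_x, alpha, beta, psi = theta
        mu = np.array([mu_x, alpha + beta * mu_x])
        sigma = np.array(
            [[phi_x, beta * phi_x], [beta * phi_x, beta**2 * phi_x + psi]]
        )
    elif spec.kind == "cfa":
        mu, lam, phi, theta_d = _cfa_matrices(spec, theta)
        sigma = lam @ phi @ lam.T + np.diag(theta_d)
    else:  # pragma: no cover - constructors only produce known kinds
        raise ConfigurationError(f"unknown model kind {spec.kind!r}")
    lo = min_eigval(sigma)
    if not np.isfinite(lo) or lo <= 0.0:
        raise InadmissibleMomentsError(
            f"implied covariance not positive definite (min eigenvalue {lo:.3e})",
            min_eigenvalue=lo,
        )
    return MomentSet(mu=mu, sigma=sigma, source="implied")


def model_jacobian(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Jacobian of the stacked moments (mu, vech Sigma) w.r.t. theta.

    Central finite differences with per-coordinate step
    ``h_j = 1e-5 * max(1, |theta_j|)``.  For the saturated model the map
    is the identity and the exact identity matrix is returned.
    """
    theta = _check_theta(spec, theta)
    if spec.kind == "saturated":
        return np.eye(spec.n_moments)
    jac = np.empty((spec.n_moments, spec.q))
    for j in range(spec.q):
        h = 1e-5 * max(1.0, abs(theta[j]))
        up = theta.copy()
        dn = theta.copy()
        up[j] += h
        dn[j] -= h
        m_up = implied_moments(spec, up).stacked()
        m_dn = implied_moments(spec, dn).stacked()
        jac[:, j] = (m_up - m_dn) / (2.0 * h)
    return jac
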