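"""Full-information maximum likelihood for incomplete multivariate-normal data.

Cases are grouped by missingness pattern; each pattern g carries its
count n_g, observed-subvector mean and ML covariance (divisor n_g).  The
observed-data log-likelihood is then

    sum_g n_g [ -(p_g/2) log 2pi - 1/2 log|Sigma_g| - 1/2 tr(Sigma_g^{-1} (S_g + d_g d_g')) ],

with d_g = xbar_g - mu_g and (mu_g, Sigma_g) the pattern submoments of
the model-implied moments — algebraically identical to the case-wise sum
over individual rows, but O(#patterns) instead of O(N) per evaluation.

Structured models are maximized by quasi-Newton iteration with variances
log-transformed (and factor correlations atanh-transformed) internally;
the unstructured (saturated) model is estimated by EM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._linalg import vech
from .exceptions import ConfigurationError, EmptyDataError
from .models import (
    CORRELATION_ROLES,
    POSITIVE_ROLES,
    ModelSpec,
    MomentSet,
    ParameterVector,
    implied_moments,
)

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Pattern:
    """One missingness pattern with its sufficient statistics."""

    mask: np.ndarray  # boolean, True = observed
    n: int
    xbar: np.ndarray  # mean of observed subvector
    s: np.ndarray  # ML covariance of observed subvector (divisor n)
    row_ids: np.ndarray

    @property
    def obs_idx(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


@dataclass(frozen=True)
class PatternSet:
    patterns: tuple[Pattern, ...]
    n_total: int
    n_dropped_empty: int
    var_names: tuple[str, ...]

    @property
    def p(self) -> int:
        return len(self.var_names)

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    @property
    def complete(self) -> bool:
        return self.n_patterns == 1 and bool(self.patterns[0].mask.all())


@dataclass
class FimlFit:
    spec: ModelSpec
    theta: ParameterVector
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_total: int

    @property
    def moments(self) -> MomentSet:
        return implied_moments(self.spec, self.theta.values)


@dataclass
class SaturatedFit:
    moments: MomentSet  # source="saturated_em"
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# patterns


def pattern_partition(data, var_names: tuple[str, ...] | None = None) -> PatternSet:
    """Group rows of an incomplete data table by missingness pattern.

    Parameters
    ----------
    data
        DataFrame or 2-d array; missing cells are NaN.
    var_names
        Column subset/order; defaults to all columns.

    All-missing rows carry no likelihood information and are dropped
    with a warning (counted in ``n_dropped_empty``).
    """
    if isinstance(data, pd.DataFrame):
        if var_names is not None:
            data = data.loc[:, list(var_names)]
        else:
            var_names = tuple(map(str, data.columns))
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        if values.ndim != 2:
            raise ConfigurationError("data must be two-dimensional")
        if var_names is None:
            var_names = tuple(f"V{i + 1}" for i in range(values.shape[1]))
    if values.shape[0] < 1 or values.shape[1] < 1:
        raise EmptyDataError("data table has no rows or no columns")

    observed = ~np.isnan(values)
    usable = observed.any(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} all-missing rows", UserWarning, stacklevel=2
        )
        logger.info("dropped %d all-missing rows", n_dropped)
    values = values[usable]
    observed = observed[usable]
    if values.shape[0] == 0:
        raise EmptyDataError("no usable rows: every case is entirely missing")

    # pack each mask into bytes for fast grouping
    keys = np.packbits(observed, axis=1)
    order = np.lexsort(keys.T[::-1])
    keys_sorted = keys[order]
    boundaries = np.flatnonzero(np.any(np.diff(keys_sorted, axis=0) != 0, axis=1)) + 1
    groups = np.split(order, boundaries)

    patterns = []
    for rows in groups:
        mask = observed[rows[0]]
        sub = values[np.ix_(rows, np.flatnonzero(mask))]
        xbar = sub.mean(axis=0)
        centered = sub - xbar
        s = centered.T @ centered / sub.shape[0]
        patterns.append(
            Pattern(
                mask=mask.copy(),
                n=len(rows),
                xbar=xbar,
                s=s,
                row_ids=np.sort(rows),
            )
        )
    patterns.sort(key=lambda pat: tuple(~pat.mask))
    return PatternSet(
        patterns=tuple(patterns),
        n_total=int(values.shape[0]),
        n_dropped_empty=n_dropped,
        var_names=tuple(var_names),
    )


# ---------------------------------------------------------------------------
# observed-data log-likelihood


def loglik_at_moments(mu: np.ndarray, sigma: np.ndarray, pats: PatternSet) -> float:
    """Observed-data log-likelihood of (mu, Sigma) from pattern statistics."""
    total = 0.0
    for pat in pats.patterns:
        idx = pat.obs_idx
        mu_g = mu[idx]
        sig_g = sigma[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(sig_g)
        if sign <= 0:
            return -np.inf
        d = pat.xbar - mu_g
        a = pat.s + np.outer(d, d)
        try:
            tr = float(np.trace(np.linalg.solve(sig_g, a)))
        except np.linalg.LinAlgError:
            return -np.inf
        total += pat.n * (-0.5 * idx.size * _LOG2PI - 0.5 * logdet - 0.5 * tr)
    return float(total)


def observed_loglik(spec: ModelSpec, theta: np.ndarray, pats: PatternSet) -> float:
    """Observed-data log-likelihood of a structured model at theta."""
    moments = implied_moments(spec, theta)
    return loglik_at_moments(moments.mu, moments.sigma, pats)


# ---------------------------------------------------------------------------
# parameter transforms (optimization scale)


def _to_internal(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    z = np.array(theta, dtype=float)
    for j, role in enumerate(spec.param_roles):
        if role in POSITIVE_ROLES:
            z[j] = np.log(theta[j])
        elif role in CORRELATION_ROLES:
            z[j] = np.arctanh(np.clip(theta[j], -0.999999, 0.999999))
    return z


def _from_internal(spec: ModelSpec, z: np.ndarray) -> np.ndarray:
    theta = np.array(z, dtype=float)
    for j, role in enumerate(spec.param_roles):
        if role in POSITIVE_ROLES:
            theta[j] = np.exp(z[j])
        elif role in CORRELATION_ROLES:
            theta[j] = np.tanh(z[j])
    return theta


# ---------------------------------------------------------------------------
# starting values


def _available_case_moments(pats: PatternSet) -> MomentSet:
    """Available-case means/variances with zero covariances (always PD)."""
    p = pats.p
    wsum = np.zeros(p)
    mean = np.zeros(p)
    m2 = np.zeros(p)
    for pat in pats.patterns:
        idx = pat.obs_idx
        wsum[idx] += pat.n
        mean[idx] += pat.n * pat.xbar
        m2[idx] += pat.n * (np.diag(pat.s) + pat.xbar**2)
    mean = np.where(wsum > 0, mean / np.maximum(wsum, 1), 0.0)
    var = np.where(wsum > 0, m2 / np.maximum(wsum, 1) - mean**2, 1.0)
    var = np.maximum(var, 1e-6)
    return MomentSet(mu=mean, sigma=np.diag(var), source="sample")


def moments_to_start(spec: ModelSpec, moments: MomentSet) -> np.ndarray:
    """Map unstructured moments to structured starting values.

    Regression uses exact moment inversion; CFA extracts loadings from
    the average within-block covariance and falls back to neutral
    defaults when the data give no usable signal.
    """
    mu, sigma = moments.mu, moments.sigma
    if spec.kind == "saturated":
        return np.concatenate([mu, vech(sigma)])
    if spec.kind == "regression":
        phi_x = max(sigma[0, 0], 1e-6)
        beta = sigma[0, 1] / phi_x
        psi = max(sigma[1, 1] - beta**2 * phi_x, 1e-6)
        alpha = mu[1] - beta * mu[0]
        return np.array([mu[0], phi_x, alpha, beta, psi])
    # CFA
    k = len(spec.factor_names)
    lmap = np.asarray(spec.loading_map)
    lam = np.full(spec.p, 0.5)
    for f in range(k):
        idx = np.flatnonzero(lmap == f)
        if idx.size >= 2:
            off = sigma[np.ix_(idx, idx)][~np.eye(idx.size, dtype=bool)]
            avg = float(np.mean(off))
            if avg > 1e-4:
                lam[idx] = np.sqrt(avg)
    phis = {}
    for j in range(k):
        for i in range(j + 1, k):
            idx_i = np.flatnonzero(lmap == i)
            idx_j = np.flatnonzero(lmap == j)
            cross = float(np.mean(sigma[np.ix_(idx_i, idx_j)]))
            li = float(np.mean(lam[idx_i]))
            lj = float(np.mean(lam[idx_j]))
            val = cross / (li * lj) if li * lj > 1e-8 else 0.3
            phis[(i, j)] = float(np.clip(val, -0.95, 0.95))
    err = np.maximum(np.diag(sigma) - lam**2, 0.05)
    start = []
    for par in spec.free_params:
        if par.role == "loading":
            v = par.name[par.name.index("[") + 1 : -1]
            start.append(lam[spec.var_names.index(v)])
        elif par.role == "factor_cov":
            pair = par.name[par.name.index("[") + 1 : -1].split(",")
            i = spec.factor_names.index(pair[0])
            j = spec.factor_names.index(pair[1])
            start.append(phis[(max(i, j), min(i, j))])
        elif par.role == "error_var":
            v = par.name[par.name.index("[") + 1 : -1]
            start.append(err[spec.var_names.index(v)])
        elif par.role == "mean":
            v = par.name[par.name.index("[") + 1 : -1]
            start.append(mu[spec.var_names.index(v)])
        else:  # pragma: no cover
            start.append(0.0)
    return np.asarray(start)


# ---------------------------------------------------------------------------
# structured fit


def fit_fiml(
    spec: ModelSpec,
    pats: PatternSet,
    start: np.ndarray | None = None,
    *,
    gtol: float = 1e-5,
    max_iter: int = 2000,
    em_start: bool = True,
) -> FimlFit:
    """Maximize the observed-data log-likelihood of a structured model.

    Quasi-Newton (L-BFGS-B) on the transformed parameter scale, with the
    objective scaled per case so tolerances do not depend on N.
    Convergence requires the per-case gradient max-norm (numeric, on the
    transformed scale) to be at or below ``gtol``.  Failures are
    reported via ``converged=False``, never raised, so that simulation
    harnesses can count them.
    """
    n = pats.n_total
    if start is None:
        if em_start and not pats.complete:
            sat = fit_saturated_em(pats)
            base = sat.moments if sat.converged else _available_case_moments(pats)
        else:
            base = (
                _complete_sample_moments(pats)
                if pats.complete
                else _available_case_moments(pats)
            )
        start = moments_to_start(spec, base)
    else:
        start = np.asarray(start, dtype=float).ravel()
        if start.size != spec.q:
            raise ConfigurationError(
                f"start vector has length {start.size}, expected q={spec.q}"
            )

    def negloglik_internal(z: np.ndarray) -> float:
        theta = _from_internal(spec, z)
        try:
            ll = observed_loglik(spec, theta, pats)
        except Exception:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll / n

    z0 = _to_internal(spec, start)
    result = optimize.minimize(
        negloglik_internal,
        z0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    # one restart from the incumbent often clears flat-tail terminations
    result2 = optimize.minimize(
        negloglik_internal,
        result.x,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-10},
    )
    if result2.fun <= result.fun:
        result = result2

    theta_hat = _from_internal(spec, result.x)
    grad = optimize.approx_fprime(result.x, negloglik_internal, 1e-7)
    grad_norm = float(np.max(np.abs(grad)))
    loglik = -result.fun * n
    converged = bool(np.isfinite(loglik)) and grad_norm <= gtol
    if not converged:
        logger.info(
            "FIML fit did not converge (grad max-norm %.3e, status %s)",
            grad_norm,
            result.message,
        )
    return FimlFit(
        spec=spec,
        theta=ParameterVector(values=theta_hat, names=spec.param_names),
        loglik=float(loglik),
        converged=converged,
        n_iter=int(result.nit) + int(result2.nit),
        grad_norm=grad_norm,
        n_total=n,
    )


def _complete_sample_moments(pats: PatternSet) -> MomentSet:
    pat = pats.patterns[0]
    return MomentSet(mu=pat.xbar.copy(), sigma=pat.s.copy(), source="sample")


# ---------------------------------------------------------------------------
# saturated EM


def fit_saturated_em(
    pats: PatternSet,
    *,
    tol_param: float = 1e-10,
    tol_loglik: float = 0.0,
    max_iter: int = 10000,
) -> SaturatedFit:
    """EM for the unstructured multivariate-normal mean and covariance.

    The E-step works entirely on pattern sufficient statistics: for a
    pattern with observed block o and missing block m, the conditional
    expectations of the missing sums are linear in the observed ones, so
    each iteration costs O(#patterns * p^3) regardless of N.

    With complete data, EM converges in one step to the sample moments.
    """
    p = pats.p
    n = pats.n_total
    if pats.complete:
        moments = _complete_sample_moments(pats)
        moments = MomentSet(moments.mu, moments.sigma, source="saturated_em")
        ll = loglik_at_moments(moments.mu, moments.sigma, pats)
        return SaturatedFit(
            moments=moments,
            loglik=ll,
            n_iter=1,
            converged=True,
            loglik_trace=np.array([ll]),
        )

    current = _available_case_moments(pats)
    mu, sigma = current.mu.copy(), current.sigma.copy()
    trace = [loglik_at_moments(mu, sigma, pats)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        for pat in pats.patterns:
            o = pat.obs_idx
            m = np.flatnonzero(~pat.mask)
            ng = pat.n
            xbar_o = pat.xbar
            t2_oo = ng * (pat.s + np.outer(xbar_o, xbar_o))
            t1_o = ng * xbar_o
            if m.size == 0:
                t1[o] += t1_o
                t2[np.ix_(o, o)] += t2_oo
                continue
            sig_oo = sigma[np.ix_(o, o)]
            sig_mo = sigma[np.ix_(m, o)]
            b = np.linalg.solve(sig_oo, sig_mo.T).T  # regression of m on o
            v = sigma[np.ix_(m, m)] - b @ sig_mo.T  # conditional covariance
            mu_o, mu_m = mu[o], mu[m]
            resid1 = t1_o - ng * mu_o  # sum of (x_o - mu_o)
            sum_m = ng * mu_m + b @ resid1
            # sum over cases of mhat_i x_oi'
            sum_mo = np.outer(mu_m, t1_o) + b @ (t2_oo - np.outer(mu_o, t1_o))
            # sum over cases of mhat_i mhat_i'
            ctr = t2_oo - np.outer(t1_o, mu_o) - np.outer(mu_o, t1_o) + ng * np.outer(mu_o, mu_o)
            sum_mm = (
                ng * v
                + ng * np.outer(mu_m, mu_m)
                + np.outer(mu_m, b @ resid1)
                + np.outer(b @ resid1, mu_m)
                + b @ ctr @ b.T
            )
            t1[o] += t1_o
            t1[m] += sum_m
            t2[np.ix_(o, o)] += t2_oo
            t2[np.ix_(m, o)] += sum_mo
            t2[np.ix_(o, m)] += sum_mo.T
            t2[np.ix_(m, m)] += sum_mm
        mu_new = t1 / n
        sigma_new = t2 / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2.0
        delta = max(
            float(np.max(np.abs(mu_new - mu))), float(np.max(np.abs(sigma_new - sigma)))
        )
        mu, sigma = mu_new, sigma_new
        trace.append(loglik_at_moments(mu, sigma, pats))
        rel_ll = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-1]))
        if delta <= tol_param or (tol_loglik > 0.0 and rel_ll <= tol_loglik):
            converged = True
            break
    return SaturatedFit(
        moments=MomentSet(mu=mu, sigma=sigma, source="saturated_em"),
        loglik=trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )
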