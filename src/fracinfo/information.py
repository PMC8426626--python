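"""Observed- and complete-data information matrices.

All matrices are on the *total-sample* scale (summed over the N cases,
never per-case), so a parameter's standard error is directly
``sqrt((J^{-1})_jj)``.  Three constructions are provided:

* ``hessian`` — negative numeric Hessian of the relevant log-likelihood
  at the estimate (observed information proper);
* ``analytic_structured`` — the dominant analytic term: the unstructured
  (h1) information in moment coordinates, evaluated at the model-implied
  moments and sandwiched between model Jacobians;
* ``analytic_unstructured`` — same sandwich, but every moment-dependent
  part evaluated at the EM (saturated) estimates instead.

The complete-data side treats a pseudo-sample of size N whose sample
moments equal the chosen moment estimates, which is how the hypothetical
complete-data standard errors are recovered from incomplete data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import duplication_matrix, min_eigval, vech_indices
from .exceptions import ConfigurationError, DifferentiationError
from .fiml import Pattern, PatternSet, loglik_at_moments, observed_loglik
from .models import ModelSpec, MomentSet, implied_moments, model_jacobian

METHODS = ("hessian", "analytic_structured", "analytic_unstructured")


@dataclass(frozen=True)
class InfoMatrix:
    """A q x q information matrix tagged with how it was built."""

    matrix: np.ndarray
    method: str  # hessian | analytic_structured | analytic_unstructured
    side: str  # observed_Y | complete_X
    moment_source: str  # implied | saturated_em
    param_names: tuple[str, ...] = ()

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", (mat + mat.T) / 2.0)

    @property
    def q(self) -> int:
        return self.matrix.shape[0]

    @property
    def is_pd(self) -> bool:
        return min_eigval(self.matrix) > 0.0

    def to_frame(self):
        import pandas as pd

        names = self.param_names or tuple(f"p{i}" for i in range(self.q))
        return pd.DataFrame(self.matrix, index=list(names), columns=list(names))


# ---------------------------------------------------------------------------
# numeric differentiation


def numeric_hessian(f, x0: np.ndarray, step_scale: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with step ``h_j = step_scale*max(1,|x_j|)``.

    Symmetrized as (H + H')/2.  Raises :class:`DifferentiationError` if
    any stencil evaluation is non-finite.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    n = x0.size
    h = step_scale * np.maximum(1.0, np.abs(x0))

    def safe_eval(x: np.ndarray, coord: int) -> float:
        val = f(x)
        if not np.isfinite(val):
            raise DifferentiationError(
                f"non-finite evaluation while differencing coordinate {coord}",
                coordinate=coord,
            )
        return float(val)

    f0 = safe_eval(x0, -1)
    hess = np.empty((n, n))
    fplus = np.empty(n)
    fminus = np.empty(n)
    for j in range(n):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        fplus[j] = safe_eval(xp, j)
        fminus[j] = safe_eval(xm, j)
        hess[j, j] = (fplus[j] - 2.0 * f0 + fminus[j]) / h[j] ** 2
    for j in range(n):
        for k in range(j + 1, n):
            xpp, xpm, xmp, xmm = x0.copy(), x0.copy(), x0.copy(), x0.copy()
            xpp[[j, k]] += [h[j], h[k]]
            xpm[j] += h[j]
            xpm[k] -= h[k]
            xmp[j] -= h[j]
            xmp[k] += h[k]
            xmm[[j, k]] -= [h[j], h[k]]
            val = (
                safe_eval(xpp, k)
                - safe_eval(xpm, k)
                - safe_eval(xmp, j)
                + safe_eval(xmm, j)
            ) / (4.0 * h[j] * h[k])
            hess[j, k] = hess[k, j] = val
    return (hess + hess.T) / 2.0


# ---------------------------------------------------------------------------
# analytic unstructured (h1) information


def _h1_pattern_blocks(pat: Pattern, mu: np.ndarray, sigma: np.ndarray):
    """Per-pattern observed-information blocks in (mu_g, vech Sigma_g)."""
    idx = pat.obs_idx
    pg = idx.size
    omega = np.linalg.inv(sigma[np.ix_(idx, idx)])
    d = pat.xbar - mu[idx]
    a = pat.s + np.outer(d, d)
    dup = duplication_matrix(pg)
    j_mm = pat.n * omega
    # cross block: n * (d'Omega kron Omega) D
    j_ms = pat.n * (np.kron((d @ omega)[None, :], omega) @ dup)
    oao = omega @ a @ omega
    j_ss_vec = 0.5 * pat.n * (np.kron(oao, omega) + np.kron(omega, oao) - np.kron(omega, omega))
    j_ss = dup.T @ j_ss_vec @ dup
    return j_mm, j_ms, j_ss


def _vech_embedding(p: int, idx: np.ndarray) -> np.ndarray:
    """Map pattern vech positions to full vech positions."""
    r_full, c_full = vech_indices(p)
    full_pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(r_full, c_full))}
    pg = idx.size
    r_sub, c_sub = vech_indices(pg)
    out = np.empty(r_sub.size, dtype=np.intp)
    for k, (a, b) in enumerate(zip(r_sub, c_sub)):
        i, j = int(idx[a]), int(idx[b])
        out[k] = full_pos[(max(i, j), min(i, j))]
    return out


def h1_observed_info(moments: MomentSet, pats: PatternSet) -> np.ndarray:
    """Observed information of the unstructured parameters (mu, vech Sigma).

    Accumulated analytically per pattern from (n_g, xbar_g, S_g) with
    the pattern submatrices of ``moments``; equals the negative numeric
    Hessian of the saturated observed-data log-likelihood evaluated at
    the same moments (that equivalence is the defining contract; this is
    the exact fast path).
    """
    p = moments.p
    if pats.p != p:
        raise ConfigurationError("moments and patterns disagree on p")
    nmom = p + p * (p + 1) // 2
    info = np.zeros((nmom, nmom))
    for pat in pats.patterns:
        idx = pat.obs_idx
        try:
            j_mm, j_ms, j_ss = _h1_pattern_blocks(pat, moments.mu, moments.sigma)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "singular pattern submatrix while building h1 information"
            ) from exc
        vech_idx = p + _vech_embedding(p, idx)
        info[np.ix_(idx, idx)] += j_mm
        info[np.ix_(idx, vech_idx)] += j_ms
        info[np.ix_(vech_idx, idx)] += j_ms.T
        info[np.ix_(vech_idx, vech_idx)] += j_ss
    return (info + info.T) / 2.0


# ---------------------------------------------------------------------------
# observed-side constructions


def observed_info_hessian(
    spec: ModelSpec, theta_hat: np.ndarray, pats: PatternSet
) -> InfoMatrix:
    """Negative numeric Hessian of the observed-data log-likelihood.

    Taken on the untransformed parameter scale at the FIML optimum.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)

    def f(theta: np.ndarray) -> float:
        return observed_loglik(spec, theta, pats)

    hess = numeric_hessian(f, theta_hat)
    return InfoMatrix(
        matrix=-hess,
        method="hessian",
        side="observed_Y",
        moment_source="implied",
        param_names=spec.param_names,
    )


def observed_info_analytic(
    spec: ModelSpec,
    theta_hat: np.ndarray,
    pats: PatternSet,
    moment_source: str = "implied",
    saturated: MomentSet | None = None,
) -> InfoMatrix:
    """Analytic observed information: Delta' * h1(M, patterns) * Delta.

    ``moment_source="implied"`` evaluates the h1 weights at the
    model-implied moments (the structured variant); ``"saturated_em"``
    uses the EM estimates of the unstructured moments instead.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    if moment_source == "implied":
        mom = implied_moments(spec, theta_hat)
        method = "analytic_structured"
    elif moment_source == "saturated_em":
        if saturated is None:
            raise ConfigurationError(
                "moment_source='saturated_em' requires the EM moments"
            )
        mom = saturated
        method = "analytic_unstructured"
    else:
        raise ConfigurationError(f"unknown moment source {moment_source!r}")
    delta = model_jacobian(spec, theta_hat)
    g = h1_observed_info(mom, pats)
    return InfoMatrix(
        matrix=delta.T @ g @ delta,
        method=method,
        side="observed_Y",
        moment_source=moment_source,
        param_names=spec.param_names,
    )


# ---------------------------------------------------------------------------
# complete-data side


def _complete_pattern_set(
    moments: MomentSet, n_total: int, var_names: tuple[str, ...]
) -> PatternSet:
    """A pseudo-sample of size N, fully observed, with the given moments."""
    p = moments.p
    pat = Pattern(
        mask=np.ones(p, dtype=bool),
        n=int(n_total),
        xbar=moments.mu.copy(),
        s=moments.sigma.copy(),
        row_ids=np.arange(int(n_total)),
    )
    return PatternSet(
        patterns=(pat,), n_total=int(n_total), n_dropped_empty=0, var_names=var_names
    )


def complete_info(
    spec: ModelSpec,
    theta_hat: np.ndarray,
    n_total: int,
    method: str = "hessian",
    saturated: MomentSet | None = None,
) -> InfoMatrix:
    """Information the complete data of size N would have carried.

    The hypothetical complete-data log-likelihood fixes the sample
    moments of a pseudo-sample of size N at M — the implied moments for
    ``hessian`` and ``analytic_structured``, the EM saturated moments
    for ``analytic_unstructured`` — and evaluates at the FIML estimates.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown information method {method!r}")
    theta_hat = np.asarray(theta_hat, dtype=float)
    if method == "analytic_unstructured":
        if saturated is None:
            raise ConfigurationError(
                "method='analytic_unstructured' requires the EM moments"
            )
        mom = saturated
        moment_source = "saturated_em"
    else:
        mom = implied_moments(spec, theta_hat)
        moment_source = "implied"
    pseudo = _complete_pattern_set(mom, n_total, spec.var_names)

    if method == "hessian":

        def f(theta: np.ndarray) -> float:
            m = implied_moments(spec, theta)
            return loglik_at_moments(m.mu, m.sigma, pseudo)

        matrix = -numeric_hessian(f, theta_hat)
    else:
        delta = model_jacobian(spec, theta_hat)
        g = h1_observed_info(mom, pseudo)
        matrix = delta.T @ g @ delta
    return InfoMatrix(
        matrix=matrix,
        method=method,
        side="complete_X",
        moment_source=moment_source,
        param_names=spec.param_names,
    )
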