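"""Per-parameter fraction of missing information (FMI) and WIF.

For parameter j, with observed-data information J_Y and hypothetical
complete-data information J_X (both on the total-sample scale),

    delta_j = 1 - (J_X^{-1})_jj / (J_Y^{-1})_jj
            = 1 - SE_{j,C}^2 / SE_{j,O}^2,

the proportion of the parameter's sampling variance attributable to the
missing data.  The width inflation factor WIF_j = SE_{j,O}/SE_{j,C}
= 1/sqrt(1 - delta_j) translates an FMI into the multiplicative widening
of the confidence interval.

Three estimator variants differ only in how the information pair is
built (see :mod:`fracinfo.information`):

* ``delta1`` — numeric Hessian on both sides;
* ``delta2`` — analytic dominant term at the model-implied moments;
* ``delta3`` — analytic dominant term at the unstructured EM moments.

The three coincide for saturated models and are asymptotically
equivalent whenever the structured model is true.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._linalg import min_eigval
from .exceptions import ConfigurationError, FracinfoError
from .fiml import FimlFit, PatternSet, SaturatedFit, fit_fiml, fit_saturated_em, pattern_partition
from .information import (
    InfoMatrix,
    complete_info,
    observed_info_analytic,
    observed_info_hessian,
)
from .models import ModelSpec

METHOD_ALIASES = {
    "delta1": "hessian",
    "delta2": "analytic_structured",
    "delta3": "analytic_unstructured",
    "hessian": "hessian",
    "analytic_structured": "analytic_structured",
    "analytic_unstructured": "analytic_unstructured",
}
METHOD_LABELS = {
    "hessian": "delta1_hessian",
    "analytic_structured": "delta2_structured",
    "analytic_unstructured": "delta3_unstructured",
}

STATUS_OK = "ok"
STATUS_NEGATIVE = "negative"
STATUS_UNDEFINED = "undefined"


def wif(delta: float) -> float:
    """Width inflation factor 1/sqrt(1 - delta) for delta in [0, 1)."""
    if not 0.0 <= delta < 1.0:
        raise ValueError(f"FMI must lie in [0, 1) to define a WIF, got {delta}")
    return 1.0 / math.sqrt(1.0 - delta)


@dataclass
class FmiResult:
    """Per-parameter FMI estimates for one computational variant."""

    method: str  # delta1_hessian | delta2_structured | delta3_unstructured
    param_names: tuple[str, ...]
    estimates: np.ndarray
    se_observed: np.ndarray
    se_complete: np.ndarray
    delta: np.ndarray
    wif: np.ndarray
    status: tuple[str, ...]
    fit: FimlFit | None = None

    @property
    def q(self) -> int:
        return len(self.param_names)

    def delta_of(self, name: str) -> float:
        return float(self.delta[self.param_names.index(name)])

    def status_of(self, name: str) -> str:
        return self.status[self.param_names.index(name)]

    def status_counts(self) -> dict[str, int]:
        out = {STATUS_OK: 0, STATUS_NEGATIVE: 0, STATUS_UNDEFINED: 0}
        for s in self.status:
            out[s] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.param_names),
                "estimate": self.estimates,
                "se_observed": self.se_observed,
                "se_complete": self.se_complete,
                "fmi": self.delta,
                "wif": self.wif,
                "status": list(self.status),
            }
        )


def _all_undefined(
    method_label: str, spec: ModelSpec, fit: FimlFit | None = None
) -> FmiResult:
    q = spec.q
    nan = np.full(q, np.nan)
    est = fit.theta.values if fit is not None else nan
    return FmiResult(
        method=method_label,
        param_names=spec.param_names,
        estimates=np.asarray(est, dtype=float),
        se_observed=nan.copy(),
        se_complete=nan.copy(),
        delta=nan.copy(),
        wif=nan.copy(),
        status=tuple([STATUS_UNDEFINED] * q),
        fit=fit,
    )


def fmi_from_info(
    j_obs: InfoMatrix,
    j_comp: InfoMatrix,
    estimates: np.ndarray | None = None,
    fit: FimlFit | None = None,
) -> FmiResult:
    """FMI per parameter from an (observed, complete) information pair.

    Non-positive-definite input marks every parameter ``undefined``;
    a negative delta (finite-sample violation of the information
    ordering) is retained for diagnostics but flagged ``negative``.
    """
    if j_obs.q != j_comp.q:
        raise ConfigurationError("information matrices differ in dimension")
    method_label = METHOD_LABELS.get(j_obs.method, j_obs.method)
    q = j_obs.q
    names = j_obs.param_names or tuple(f"p{i}" for i in range(q))
    if estimates is None:
        estimates = np.full(q, np.nan)
    estimates = np.asarray(estimates, dtype=float)

    if min_eigval(j_obs.matrix) <= 0.0 or min_eigval(j_comp.matrix) <= 0.0:
        nan = np.full(q, np.nan)
        return FmiResult(
            method=method_label,
            param_names=names,
            estimates=estimates,
            se_observed=nan.copy(),
            se_complete=nan.copy(),
            delta=nan.copy(),
            wif=nan.copy(),
            status=tuple([STATUS_UNDEFINED] * q),
            fit=fit,
        )
    var_obs = np.diag(np.linalg.inv(j_obs.matrix))
    var_comp = np.diag(np.linalg.inv(j_comp.matrix))
    delta = 1.0 - var_comp / var_obs
    status = []
    wifs = np.full(q, np.nan)
    for j in range(q):
        if not np.isfinite(delta[j]):
            status.append(STATUS_UNDEFINED)
        elif delta[j] < 0.0:
            status.append(STATUS_NEGATIVE)
        else:
            status.append(STATUS_OK)
            wifs[j] = wif(float(delta[j]))
    return FmiResult(
        method=method_label,
        param_names=names,
        estimates=estimates,
        se_observed=np.sqrt(var_obs),
        se_complete=np.sqrt(var_comp),
        delta=delta,
        wif=wifs,
        status=tuple(status),
        fit=fit,
    )


def _info_pair(
    spec: ModelSpec,
    fit: FimlFit,
    pats: PatternSet,
    method: str,
    saturated: SaturatedFit | None,
) -> tuple[InfoMatrix, InfoMatrix]:
    theta = fit.theta.values
    sat_moments = saturated.moments if saturated is not None else None
    if method == "hessian":
        j_obs = observed_info_hessian(spec, theta, pats)
        j_comp = complete_info(spec, theta, pats.n_total, method="hessian")
    elif method == "analytic_structured":
        j_obs = observed_info_analytic(spec, theta, pats, moment_source="implied")
        j_comp = complete_info(spec, theta, pats.n_total, method="analytic_structured")
    else:
        j_obs = observed_info_analytic(
            spec, theta, pats, moment_source="saturated_em", saturated=sat_moments
        )
        j_comp = complete_info(
            spec,
            theta,
            pats.n_total,
            method="analytic_unstructured",
            saturated=sat_moments,
        )
    return j_obs, j_comp


def fmi_analysis(
    spec: ModelSpec,
    data,
    methods: tuple[str, ...] = ("delta1", "delta2", "delta3"),
    *,
    var_names: tuple[str, ...] | None = None,
    start: np.ndarray | None = None,
) -> dict[str, FmiResult]:
    """Fit a model by FIML and compute FMIs for the requested variants.

    The FIML fit (and, when needed, the saturated EM fit) is shared
    across variants.  A non-converged fit or an information-matrix
    failure yields all-``undefined`` results, never an exception, so
    simulation harnesses can account for failures.
    """
    canonical = []
    for m in methods:
        if m not in METHOD_ALIASES:
            raise ConfigurationError(f"unknown FMI method {m!r}")
        canonical.append(METHOD_ALIASES[m])
    if not canonical:
        raise ConfigurationError("at least one FMI method must be requested")

    pats = data if isinstance(data, PatternSet) else pattern_partition(data, var_names)
    fit = fit_fiml(spec, pats, start=start)
    needs_sat = "analytic_unstructured" in canonical
    saturated = None
    if needs_sat:
        saturated = fit_saturated_em(pats)

    out: dict[str, FmiResult] = {}
    for m in canonical:
        label = METHOD_LABELS[m]
        if not fit.converged or (
            m == "analytic_unstructured"
            and (saturated is None or not saturated.converged)
        ):
            out[label] = _all_undefined(label, spec, fit)
            continue
        try:
            j_obs, j_comp = _info_pair(spec, fit, pats, m, saturated)
            out[label] = fmi_from_info(j_obs, j_comp, fit.theta.values, fit)
        except FracinfoError:
            out[label] = _all_undefined(label, spec, fit)
        except np.linalg.LinAlgError:
            out[label] = _all_undefined(label, spec, fit)
    return out


def compute_fmi(
    spec: ModelSpec,
    data,
    method: str = "delta1",
    *,
    var_names: tuple[str, ...] | None = None,
    start: np.ndarray | None = None,
) -> FmiResult:
    """Single-variant convenience wrapper around :func:`fmi_analysis`."""
    if method not in METHOD_ALIASES:
        raise ConfigurationError(f"unknown FMI method {method!r}")
    label = METHOD_LABELS[METHOD_ALIASES[method]]
    return fmi_analysis(spec, data, (method,), var_names=var_names, start=start)[label]
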