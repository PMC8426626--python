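"""Monte-Carlo evaluation harness for the sample FMI estimators.

A *condition* crosses a population model (regression or two-factor), a
missingness mechanism (MCAR, linear MAR, nonlinear MAR), a per-variable
missing rate and a sample size.  For each condition the harness:

1. computes pseudo-population FMIs from a single very large sample
   (N = 1,000,000 by default), checking that the three computational
   variants agree there;
2. runs independent replications, fitting each simulated dataset by
   FIML and computing all three FMI variants;
3. summarizes raw bias, RMSE and the 95% equal-tailed-interval (ETI)
   width of each estimator against the pseudo-population value,
   excluding replicates whose FMI was negative or undefined (failed
   fits and broken information matrices are counted, not averaged in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FracinfoError
from .fmi import METHOD_LABELS, STATUS_OK, fmi_analysis
from .models import ModelSpec, make_regression_model, make_two_factor_model
from .simulate import (
    Mechanism,
    regression_mechanism,
    simulate_dataset,
    two_factor_mechanism,
)

#: parameters whose FMI the study designs track
FOCAL_PARAMS = {
    "regression": ("beta",),
    "two_factor": ("lambda[X2]", "phi[F2,F1]"),
}

METHODS = tuple(METHOD_LABELS.values())


@dataclass(frozen=True)
class Condition:
    model: str  # regression | two_factor
    mechanism_type: str  # mcar | mar_linear | mar_nonlinear
    pi_mis: float
    n: int
    n_rep: int = 1000
    base_seed: int = 0

    def mechanism(self) -> Mechanism:
        if self.model == "regression":
            return regression_mechanism(self.mechanism_type, self.pi_mis)
        if self.model == "two_factor":
            return two_factor_mechanism(self.mechanism_type, self.pi_mis)
        raise ConfigurationError(f"unknown model {self.model!r}")

    def spec(self) -> ModelSpec:
        return (
            make_regression_model()
            if self.model == "regression"
            else make_two_factor_model()
        )

    def focal_params(self) -> tuple[str, ...]:
        return FOCAL_PARAMS[self.model]


@dataclass
class PopulationFmi:
    """Pseudo-population FMIs from one very large sample."""

    delta: dict  # parameter -> delta (from the unstructured variant)
    max_discrepancy: float  # max over parameters of |delta1 - delta3| etc.
    n_pop: int
    seed: int


@dataclass
class ConditionSummary:
    condition: Condition
    summary: pd.DataFrame  # rows: (parameter, method) with bias/rmse/eti + counts
    replicates: pd.DataFrame  # per-replicate deltas and statuses
    n_nonconverged: int

    def row(self, parameter: str, method: str) -> pd.Series:
        mask = (self.summary["parameter"] == parameter) & (
            self.summary["method"] == method
        )
        sub = self.summary[mask]
        if sub.empty:
            raise KeyError((parameter, method))
        return sub.iloc[0]


# ---------------------------------------------------------------------------
# evaluation criteria


def bias(estimates, delta_pop: float) -> float:
    """Mean of the estimates minus the pseudo-population value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("bias of an empty estimate vector is undefined")
    return float(estimates.mean() - delta_pop)


def rmse(estimates, delta_pop: float) -> float:
    """Root mean squared deviation from the pseudo-population value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("rmse of an empty estimate vector is undefined")
    return float(np.sqrt(np.mean((estimates - delta_pop) ** 2)))


def eti_width(estimates, level: float = 0.95) -> float:
    """Width of the equal-tailed interval of the Monte-Carlo draws.

    Linear-interpolation quantiles; for level 0.95 this is the distance
    between the 2.5th and 97.5th percentiles.
    """
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValueError("eti_width needs at least two values")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(hi - lo)


# ---------------------------------------------------------------------------
# pseudo-population FMI


def pseudo_population_fmi(
    model: str,
    mechanism_type: str | None,
    pi_mis: float | None,
    n_pop: int = 1_000_000,
    seed: int = 0,
    max_discrepancy_tol: float = 0.005,
) -> PopulationFmi:
    """FMIs from a single N = n_pop sample (the asymptotic stand-in).

    All three variants are computed; the population fit must converge
    (a hard error otherwise) and the variants must agree within
    ``max_discrepancy_tol`` on every parameter.  The returned deltas are
    the unstructured-variant values.
    """
    spec = (
        make_regression_model() if model == "regression" else make_two_factor_model()
    )
    if mechanism_type is None or pi_mis is None or pi_mis == 0.0:
        from .simulate import (
            simulate_regression_population,
            simulate_two_factor_population,
        )

        gen = (
            simulate_regression_population
            if model == "regression"
            else simulate_two_factor_population
        )
        data = gen(n_pop, seed)
    else:
        cond = Condition(model, mechanism_type, pi_mis, n_pop, base_seed=seed)
        data = simulate_dataset(model, cond.mechanism(), n_pop, seed).observed
    results = fmi_analysis(spec, data)
    fit = next(iter(results.values())).fit
    if fit is None or not fit.converged:
        raise FracinfoError("population-scale FIML fit failed to converge")
    deltas = np.stack([results[m].delta for m in METHODS])
    if not np.all(np.isfinite(deltas)):
        raise FracinfoError("population-scale FMI computation produced NaNs")
    disc = float(np.max(np.abs(deltas[0] - deltas[2])))
    disc = max(disc, float(np.max(np.abs(deltas[1] - deltas[2]))))
    if disc > max_discrepancy_tol:
        raise FracinfoError(
            f"FMI variants disagree at population scale (max |diff| {disc:.4f})"
        )
    d3 = results[METHOD_LABELS["analytic_unstructured"]]
    delta_map = dict(zip(d3.param_names, map(float, d3.delta)))
    return PopulationFmi(
        delta=delta_map, max_discrepancy=disc, n_pop=n_pop, seed=seed
    )


# ---------------------------------------------------------------------------
# replication loop


def run_replicates(cond: Condition) -> tuple[pd.DataFrame, int]:
    """Run the replicates of one condition; return the ledger.

    One row per (replicate, parameter, method) with the FMI value and
    its status.  A non-converged fit marks every parameter undefined
    for that replicate.
    """
    spec = cond.spec()
    mech = cond.mechanism()
    focal = cond.focal_params()
    rows = []
    n_nonconverged = 0
    for i in range(cond.n_rep):
        seed = cond.base_seed + i
        ds = simulate_dataset(cond.model, mech, cond.n, seed)
        results = fmi_analysis(spec, ds.observed)
        fit = next(iter(results.values())).fit
        if fit is None or not fit.converged:
            n_nonconverged += 1
        for method, res in results.items():
            for name in focal:
                rows.append(
                    {
                        "replicate": i,
                        "seed": seed,
                        "parameter": name,
                        "method": method,
                        "fmi": res.delta_of(name),
                        "status": res.status_of(name),
                    }
                )
    return pd.DataFrame(rows), n_nonconverged


def summarize_replicates(
    ledger: pd.DataFrame, delta_pop: dict, n_rep: int
) -> pd.DataFrame:
    """Bias/RMSE/ETI per (parameter, method) over status-ok replicates."""
    rows = []
    for (name, method), grp in ledger.groupby(["parameter", "method"], sort=True):
        ok = grp[grp["status"] == STATUS_OK]["fmi"].to_numpy()
        n_neg = int((grp["status"] == "negative").sum())
        n_und = int((grp["status"] == "undefined").sum())
        pop = float(delta_pop[name])
        rows.append(
            {
                "parameter": name,
                "method": method,
                "delta_pop": pop,
                "bias": bias(ok, pop) if ok.size else np.nan,
                "rmse": rmse(ok, pop) if ok.size else np.nan,
                "eti_width": eti_width(ok) if ok.size >= 2 else np.nan,
                "n_ok": int(ok.size),
                "n_negative": n_neg,
                "n_undefined": n_und,
                "n_rep": n_rep,
            }
        )
    return pd.DataFrame(rows)


def run_condition(
    cond: Condition, delta_pop: dict | None = None, pop_seed: int | None = None
) -> ConditionSummary:
    """Run a full condition: replicates plus summary against delta_pop.

    ``delta_pop`` may be supplied (e.g. shared across sample sizes);
    otherwise it is computed from a fresh N = 1,000,000 sample seeded
    independently of the replicate stream.
    """
    if delta_pop is None:
        if pop_seed is None:
            pop_seed = cond.base_seed + 1_000_003
        pop = pseudo_population_fmi(
            cond.model, cond.mechanism_type, cond.pi_mis, seed=pop_seed
        )
        delta_pop = pop.delta
    ledger, n_nonconverged = run_replicates(cond)
    summary = summarize_replicates(ledger, delta_pop, cond.n_rep)
    return ConditionSummary(
        condition=cond,
        summary=summary,
        replicates=ledger,
        n_nonconverged=n_nonconverged,
    )
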