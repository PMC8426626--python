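"""Population data generators and MCAR / MAR missingness mechanisms.

Two population models are built in:

* regression — Y = 0.4*X + E with X, Y standard normal (so E has
  variance 1 - 0.4^2);
* two-factor — eight unit-variance indicators, four per factor, all
  loadings 0.49, factor correlation 0.4, error variances 1 - 0.49^2.

Missingness is organized in *blocks*: a block is a set of target
variables that go missing together (one Bernoulli draw per case per
block), optionally driven by a conditioning sum of fully observed
variables.  In the two-factor design the incomplete indicators of a
factor form one block (X2, X4 driven by C_X = X1 + X3; Y2, Y4 by
C_Y = Y1 + Y3), so the pair is either jointly missing or jointly
observed on any given case; the regression design has the single block
{X} driven by Y.  Conditioning variables are always fully observed,
keeping MAR mechanisms MAR.

Mechanism types:

* ``mcar`` — each block independently missing with probability pi_mis;
* ``mar_linear`` — one cutoff on the standardized conditioner: missing
  with probability pi1 above it, pi2 below;
* ``mar_nonlinear`` — symmetric cutoff pair: pi1 outside, pi2 inside.

Cutoffs are theoretical population percentiles chosen so the marginal
missing rate is exactly pi_mis: with pi_c = (pi_mis - pi1)/(pi2 - pi1),
the linear cutoff is Phi^{-1}(pi_c) and the nonlinear pair is
+/- Phi^{-1}(0.5 + 0.5*pi_c).  Conditioning sums are standardized by
their theoretical SD (sqrt(2 + 2*lambda^2) for the sum of two
indicators of one factor), so the standardized conditioner is exactly
standard normal and the cutoffs transfer unchanged across designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MechanismError

BETA = 0.4
LAMBDA = 0.49
PHI = 0.4

MECHANISM_TYPES = ("mcar", "mar_linear", "mar_nonlinear")


@dataclass(frozen=True)
class Block:
    """Targets that share one missingness draw, plus their conditioner."""

    targets: tuple[str, ...]
    conditioner: tuple[str, ...] = ()  # empty for MCAR
    conditioner_sd: float = 1.0  # theoretical SD of the conditioning sum

    def __post_init__(self):
        if not self.targets:
            raise MechanismError("a missingness block needs at least one target")
        overlap = set(self.targets) & set(self.conditioner)
        if overlap:
            raise MechanismError(
                f"variables {sorted(overlap)} are both target and conditioner "
                "(the mechanism would be MNAR)"
            )
        if self.conditioner_sd <= 0:
            raise MechanismError("conditioner_sd must be positive")


@dataclass(frozen=True)
class Mechanism:
    """A missingness mechanism over one or more blocks."""

    type: str
    pi_mis: float
    blocks: tuple[Block, ...]
    pi1: float = 0.9
    pi2: float = 0.1

    def __post_init__(self):
        if self.type not in MECHANISM_TYPES:
            raise MechanismError(f"unknown mechanism type {self.type!r}")
        if not 0.0 < self.pi_mis < 1.0:
            raise MechanismError("pi_mis must lie in (0, 1)")
        if not self.blocks:
            raise MechanismError("mechanism needs at least one block")
        targets = [t for b in self.blocks for t in b.targets]
        if len(set(targets)) != len(targets):
            raise MechanismError("a variable appears in more than one block")
        if self.type != "mcar":
            if not (self.pi2 < self.pi_mis < self.pi1):
                raise MechanismError(
                    f"need pi2 < pi_mis < pi1, got {self.pi2} / {self.pi_mis} / {self.pi1}"
                )
            for b in self.blocks:
                if not b.conditioner:
                    raise MechanismError(
                        f"block {b.targets} has no conditioner for a MAR mechanism"
                    )

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(t for b in self.blocks for t in b.targets)

    @property
    def pi_c(self) -> float:
        """Percentile mass of the low-risk region."""
        if self.type == "mcar":
            raise MechanismError("pi_c is undefined for MCAR")
        return (self.pi_mis - self.pi1) / (self.pi2 - self.pi1)

    @property
    def cutoffs(self) -> tuple[float, ...]:
        return mar_cutoffs(self.pi_mis, self.pi1, self.pi2, self.type)

    def manifest(self) -> dict:
        out = {
            "type": self.type,
            "pi_mis": self.pi_mis,
            "blocks": [
                {
                    "targets": list(b.targets),
                    "conditioner": list(b.conditioner),
                    "conditioner_sd": b.conditioner_sd,
                }
                for b in self.blocks
            ],
        }
        if self.type != "mcar":
            out.update(
                {
                    "pi1": self.pi1,
                    "pi2": self.pi2,
                    "pi_c": self.pi_c,
                    "cutoffs": list(self.cutoffs),
                }
            )
        return out


@dataclass(frozen=True)
class SimulatedDataset:
    complete: pd.DataFrame
    observed: pd.DataFrame
    mechanism: Mechanism
    seed: int
    realized_rates: dict

    def write_csv(self, complete_path, observed_path, na_token: str = "NA") -> None:
        self.complete.to_csv(complete_path, index=False)
        self.observed.to_csv(observed_path, index=False, na_rep=na_token)


def mar_cutoffs(pi_mis: float, pi1: float, pi2: float, type: str) -> tuple[float, ...]:
    """Theoretical standard-normal cutoff(s) giving marginal rate pi_mis.

    Linear: single cutoff Phi^{-1}(pi_c) with the high-miss region
    above.  Nonlinear: symmetric pair +/- Phi^{-1}(0.5 + 0.5*pi_c) with
    the high-miss region outside.  The marginal rate identity
    pi1*(1 - pi_c) + pi2*pi_c = pi_mis holds by construction.
    """
    if not (pi2 < pi_mis < pi1):
        raise MechanismError(f"need pi2 < pi_mis < pi1, got {pi2} / {pi_mis} / {pi1}")
    pi_c = (pi_mis - pi1) / (pi2 - pi1)
    if type == "mar_linear":
        return (float(stats.norm.ppf(pi_c)),)
    if type == "mar_nonlinear":
        hi = float(stats.norm.ppf(0.5 + 0.5 * pi_c))
        return (-hi, hi)
    raise MechanismError(f"no cutoffs for mechanism type {type!r}")


# ---------------------------------------------------------------------------
# population models


def simulate_regression_population(
    n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """X ~ N(0,1); Y = 0.4*X + E with Var(E) = 1 - 0.16, so Var(Y) = 1."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n) * np.sqrt(1.0 - BETA**2)
    y = BETA * x + e
    return pd.DataFrame({"X": x, "Y": y})


def simulate_two_factor_population(
    n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Eight unit-variance indicators of two factors correlated at 0.4."""
    rng = np.random.default_rng(seed)
    factor_cov = np.array([[1.0, PHI], [PHI, 1.0]])
    factors = rng.multivariate_normal(np.zeros(2), factor_cov, size=n)
    err_sd = np.sqrt(1.0 - LAMBDA**2)
    cols = {}
    for i in range(4):
        cols[f"X{i + 1}"] = LAMBDA * factors[:, 0] + err_sd * rng.standard_normal(n)
    for i in range(4):
        cols[f"Y{i + 1}"] = LAMBDA * factors[:, 1] + err_sd * rng.standard_normal(n)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# the two study mechanisms


def regression_mechanism(type: str, pi_mis: float) -> Mechanism:
    """Missingness on X only, conditioned on the fully observed Y."""
    cond = () if type == "mcar" else ("Y",)
    return Mechanism(
        type=type,
        pi_mis=pi_mis,
        blocks=(Block(targets=("X",), conditioner=cond, conditioner_sd=1.0),),
    )


def two_factor_mechanism(type: str, pi_mis: float) -> Mechanism:
    """Block missingness on (X2, X4) and (Y2, Y4).

    Each pair shares one missingness draw per case; under MAR the X
    block is driven by C_X = X1 + X3 and the Y block by C_Y = Y1 + Y3,
    standardized by the theoretical SD sqrt(2 + 2*lambda^2).
    """
    sd = float(np.sqrt(2.0 + 2.0 * LAMBDA**2))
    cx = () if type == "mcar" else ("X1", "X3")
    cy = () if type == "mcar" else ("Y1", "Y3")
    return Mechanism(
        type=type,
        pi_mis=pi_mis,
        blocks=(
            Block(targets=("X2", "X4"), conditioner=cx, conditioner_sd=sd),
            Block(targets=("Y2", "Y4"), conditioner=cy, conditioner_sd=sd),
        ),
    )


# ---------------------------------------------------------------------------
# imposing missingness


def impose_missingness(
    complete: pd.DataFrame, mech: Mechanism, seed: int | np.random.Generator
) -> SimulatedDataset:
    """Apply a mechanism to complete data, returning both tables.

    One uniform draw per (case, block): all targets of a block share
    their missingness indicator, while distinct blocks are
    conditionally independent given their conditioners.
    """
    for t in mech.targets:
        if t not in complete.columns:
            raise MechanismError(f"target {t!r} not found in data")
    rng = np.random.default_rng(seed)
    n = len(complete)
    observed = complete.copy()
    realized = {}
    for block in mech.blocks:
        if mech.type == "mcar":
            prob = np.full(n, mech.pi_mis)
        else:
            for cv in block.conditioner:
                if cv not in complete.columns:
                    raise MechanismError(f"conditioner {cv!r} not found in data")
                if complete[cv].isna().any():
                    raise MechanismError(f"conditioner {cv!r} contains missing values")
            z = (
                complete[list(block.conditioner)].sum(axis=1).to_numpy()
                / block.conditioner_sd
            )
            cuts = mech.cutoffs
            if mech.type == "mar_linear":
                high_risk = z > cuts[0]
            else:
                high_risk = (z > cuts[1]) | (z < cuts[0])
            prob = np.where(high_risk, mech.pi1, mech.pi2)
        miss = rng.random(n) < prob
        for t in block.targets:
            observed.loc[miss, t] = np.nan
            realized[t] = float(miss.mean())
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return SimulatedDataset(
        complete=complete,
        observed=observed,
        mechanism=mech,
        seed=int(seed_val),
        realized_rates=realized,
    )


def simulate_dataset(
    model: str, mech: Mechanism, n: int, seed: int
) -> SimulatedDataset:
    """Generate complete data and impose a mechanism, one master seed.

    Complete-data generation and missingness imposition consume
    disjoint substreams of the master seed, so mechanisms can be
    swapped while holding the complete data fixed.
    """
    ss = np.random.SeedSequence(seed)
    child_data, child_miss = ss.spawn(2)
    if model == "regression":
        complete = simulate_regression_population(n, np.random.default_rng(child_data))
    elif model == "two_factor":
        complete = simulate_two_factor_population(n, np.random.default_rng(child_data))
    else:
        raise MechanismError(f"unknown population model {model!r}")
    ds = impose_missingness(complete, mech, np.random.default_rng(child_miss))
    return SimulatedDataset(
        complete=ds.complete,
        observed=ds.observed,
        mechanism=mech,
        seed=seed,
        realized_rates=ds.realized_rates,
    )
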