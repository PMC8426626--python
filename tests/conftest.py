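import numpy as np
import pandas as pd
import pytest

import fracinfo as fi


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def bivariate_incomplete():
    """A moderate bivariate dataset with linear-MAR missingness on X."""
    mech = fi.regression_mechanism("mar_linear", 0.4)
    return fi.simulate_dataset("regression", mech, 400, seed=7).observed


@pytest.fixture
def scattered_incomplete(rng):
    """50 x 3 correlated normal data with scattered missing cells."""
    chol = np.linalg.cholesky(
        np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.4], [0.2, 0.4, 1.5]])
    )
    data = rng.standard_normal((50, 3)) @ chol.T + np.array([0.5, -1.0, 2.0])
    mask = rng.random((50, 3)) < 0.25
    mask[mask.all(axis=1)] = False
    data[mask] = np.nan
    return pd.DataFrame(data, columns=["A", "B", "C"])


class _PopulationCells:
    """Lazily computed N=1e6 pseudo-population cells, cached per session.

    Each cell is one large simulated dataset analyzed with all three FMI
    variants; tests share cells so the expensive two-factor fits run
    once.
    """

    N_POP = 1_000_000
    SEED = 20240917

    def __init__(self):
        self._cache = {}

    def __call__(self, model: str, mechanism: str, rate: float):
        key = (model, mechanism, rate)
        if key not in self._cache:
            spec = (
                fi.make_regression_model()
                if model == "regression"
                else fi.make_two_factor_model()
            )
            mech = (
                fi.regression_mechanism(mechanism, rate)
                if model == "regression"
                else fi.two_factor_mechanism(mechanism, rate)
            )
            ds = fi.simulate_dataset(model, mech, self.N_POP, self.SEED)
            self._cache[key] = fi.fmi_analysis(spec, ds.observed)
        return self._cache[key]


@pytest.fixture(scope="session")
def population_cells():
    return _PopulationCells()
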