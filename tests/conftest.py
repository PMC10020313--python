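import numpy as np
import pandas as pd
import pytest

import dispersim as ds
from dispersim import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    # 20 x 20 cells of 100 m, origin (0, 2000)
    return ds.GridSpec(x0=0.0, y0=2000.0, res=100.0, ncols=20, nrows=20)


@pytest.fixture
def small_stack(small_grid):
    r = np.random.default_rng(99)
    gradient = np.tile(np.linspace(0.0, 1.0, small_grid.ncols), (small_grid.nrows, 1))
    return ds.CovariateStack(
        grid=small_grid,
        layers={"gradient": gradient, "noise": r.normal(size=small_grid.shape)},
    )


@pytest.fixture
def flat_stack():
    """Homogeneous landscape with huge extent for unconstrained walks."""
    grid = ds.GridSpec(x0=-500_000.0, y0=500_000.0, res=5000.0, ncols=200, nrows=200)
    return ds.CovariateStack(grid=grid, layers={"flat": np.zeros(grid.shape)})


@pytest.fixture
def flat_model():
    """Null movement model (beta = 0) with the field-typical gamma kernel."""
    return ds.MovementModel(
        terms=["flat"],
        beta=np.zeros(1),
        gamma=ds.GammaStepLength(0.37, 6308.0),
        n_random=24,
    )


@pytest.fixture(scope="session")
def tiny_scenario():
    return synth.SyntheticScenario(
        seed=7, ncols=60, nrows=60, n_individuals=4, n_steps=40, dropout_rate=0.0
    )


@pytest.fixture(scope="session")
def tiny_landscape(tiny_scenario):
    return synth.make_landscape(tiny_scenario)


def nll_bruteforce(frame: pd.DataFrame, terms, beta) -> float:
    """Independent conditional-logistic likelihood: per-stratum enumeration."""
    import math

    beta = list(beta)
    total = 0.0
    for _, grp in frame.groupby("stratum"):
        scores = []
        case_score = None
        for _, row in grp.iterrows():
            eta = 0.0
            for b, term in zip(beta, terms):
                v = 1.0
                for part in term.split(":"):
                    v *= row[part]
                eta += b * v
            w = math.exp(eta)
            scores.append(w)
            if row["case"] == 1:
                case_score = w
        total -= math.log(case_score / sum(scores))
    return total
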