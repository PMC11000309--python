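import logging

import numpy as np
import pytest

from respseg import RunConfig, SimulationConfig, make_trial_triplet
from respseg.cv import GridConfig

logging.getLogger("respseg").setLevel(logging.WARNING)

# Reduced technique grid for simulation studies: one representative of the
# cheap families, so multi-replicate studies stay fast while still
# exercising the search/selection machinery.
SMALL_GRID = GridConfig(families=("HoldOut", "KFold", "StratifiedKFold"),
                        kfold_k=(5, 10), stratified_k=(3, 5))


def small_run_config(seed=20240408, **kwargs) -> RunConfig:
    return RunConfig(grid=SMALL_GRID, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def triplet():
    """Two small training trials + one test trial with informative covariates."""
    cfg = SimulationConfig(triplet_sizes=(120, 100, 150))
    return make_trial_triplet(cfg, seed=11)


@pytest.fixture(scope="session")
def small_trial(triplet):
    return triplet[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20240408)


def logistic_xy(rng, n=200, slopes=(0.8, -0.5, 0.4, -0.3, 0.6, 1.0, -0.7),
                intercept=-0.2):
    """Simulated design/outcome with known logistic coefficients."""
    slopes = np.asarray(slopes, dtype=float)
    X = rng.normal(size=(n, slopes.shape[0]))
    p = 1.0 / (1.0 + np.exp(-(X @ slopes + intercept)))
    y = rng.binomial(1, p)
    return X, y
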