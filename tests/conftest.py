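import dataclasses

import numpy as np
import pytest

from survsel.data import SurvivalDataset
from survsel.sim_designs import SimulationDesign, generate_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_dataset(seed=0, n=120, p=4, beta=(0.6, -0.4, 0.0, 0.2), censor_scale=1.2):
    """Small independent-covariate dataset with a known signal."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)[:p]
    X = rng.standard_normal((n, p))
    T = rng.exponential(np.exp(-(X @ beta)))
    C = rng.exponential(censor_scale, n)
    return SurvivalDataset(time=np.minimum(T, C), event=(T <= C).astype(int), X=X)


@pytest.fixture
def toy_data():
    return toy_dataset()


@pytest.fixture
def strong_toy_data():
    """n=400, two strong independent signals among noise."""
    return toy_dataset(seed=3, n=400, p=6, beta=(1.0, -1.0, 0, 0, 0, 0))


#: A shrunken analogue of the benchmark designs: correlated blocks, sparse
#: negative effects, ~50% censoring; small enough for fast unit tests.
SMALL_DESIGN = SimulationDesign(
    design_id=1, n=150, p=30, q=3, beta_range=(-1.0, -0.5), rho=0.9,
    block_size=10, censor_rate_c=0.17, seed=0)


@pytest.fixture(scope="session")
def small_replicate():
    return generate_replicate(SMALL_DESIGN, seed=11)


@pytest.fixture(scope="session")
def medium_replicate():
    """Closer to the benchmark designs but still fast: n=250, p=60."""
    design = dataclasses.replace(
        SMALL_DESIGN, n=250, p=60, q=4, block_size=20, seed=1)
    return generate_replicate(design, seed=21)
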