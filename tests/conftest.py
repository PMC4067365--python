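import numpy as np
import pytest

from ecotypesim import SimulationConfig

# the four stable phenotypes of the exemplar radiation (affinity vectors)
BLUE = [0, 0, 0.3, 0, 0.4, 0, 0, 0, 0.2]
RED = [0, 0.3, 0.3, 0, 0.3, 0, 0.1, 0, 0.1]
GREEN = [0, 0.1, 0, 0.4, 0, 0, 0.4, 0, 0]
CYAN = [0.2, 0.1, 0, 0, 0, 0.4, 0, 0.4, 0.1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exemplar_phenotypes():
    return [BLUE, RED, GREEN, CYAN]


@pytest.fixture
def small_config():
    """A cheap configuration for unit-scale dynamics tests."""
    return SimulationConfig(
        N=100, R=9, mu=0.05, lam=1e-3, sigma1=1.0, sigma2=0.1,
        updates=500, seed=7, record_ancestry=False,
    )
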