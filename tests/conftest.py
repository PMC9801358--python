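import numpy as np
import pytest

from neighvisit import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_tracts=120,
        n_pois_per_category={"fast_food": 20, "fitness": 12, "nature_park": 8},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
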