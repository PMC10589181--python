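import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from litterfate.synthetic_data import (ExperimentDesign, NoiseModel,
                                       SimulationConfig, generate_experiment)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=12345)


@pytest.fixture(scope="session")
def noisefree_dataset(design):
    cfg = SimulationConfig(seed=7, noise=NoiseModel.zero())
    return generate_experiment(design, cfg)


@pytest.fixture(scope="session")
def noisy_dataset(design, config):
    return generate_experiment(design, config)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
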