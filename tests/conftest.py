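import numpy as np
import pytest

from agrifuse.config import ScenarioConfig
from agrifuse.synthetic_field import generate_scenario


@pytest.fixture
def default_config():
    return ScenarioConfig()


@pytest.fixture
def scenario(default_config):
    return generate_scenario(default_config)


@pytest.fixture
def noiseless_scenario():
    return generate_scenario(ScenarioConfig(noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
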