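import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tostab.config import SignalParams, StudyBlock, StudyConfig
from tostab.synthetic import generate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_config() -> StudyConfig:
    return StudyConfig(studies=(StudyBlock(2, 1, 2),))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_study(tiny_config, SignalParams(), seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
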