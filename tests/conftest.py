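import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pankov as pk

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> pk.EnergyParameters:
    return pk.default_parameters()


@pytest.fixture(scope="session")
def score_cfg() -> pk.ScoreConfig:
    return pk.ScoreConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
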