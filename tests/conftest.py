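import numpy as np
import pytest
from hypothesis import settings

from wcpair.experiments import case_config
from wcpair.model import ModelConfig

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160920)


@pytest.fixture(scope="session")
def case_a():
    return case_config("a")


@pytest.fixture(scope="session")
def case_c():
    return case_config("c")


def random_config(rng) -> ModelConfig:
    """A random, physically plausible parameter set for property tests."""
    return ModelConfig.from_dict({
        "a": rng.uniform(0.01, 2.0),
        "b": rng.uniform(0.5, 25.0),
        "c": rng.uniform(0.5, 15.0),
        "d": rng.uniform(0.01, 2.0),
        "e": rng.uniform(0.5, 12.0),
        "w": rng.uniform(0.5, 15.0),
        "alpha1": rng.uniform(0.0, 4.0),
        "alpha2": rng.uniform(0.0, 4.0),
        "beta1": rng.uniform(0.0, 4.0),
        "beta2": rng.uniform(0.0, 4.0),
        "I1": rng.uniform(-2.0, 2.0),
        "I2": rng.uniform(-2.0, 2.0),
        "J1": rng.uniform(-2.0, 2.0),
        "J2": rng.uniform(-2.0, 2.0),
    })
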