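import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import methclass as mc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study conditions for fast unit tests."""
    return mc.SimConfig(
        n_cpgs=600,
        n_differential=50,
        n_tumors_per_subtype=12,
        n_normals=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return mc.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def train_test(small_config):
    return mc.simulate_train_test(small_config, with_expression=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
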