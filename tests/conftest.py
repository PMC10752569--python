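import numpy as np
import pytest

from mutorque.optimization import GAConfig
from mutorque.signal_processing import SignalConfig
from mutorque.synthetic_data import PoolConfig, generate_trial_bundle


@pytest.fixture(scope="session")
def signal_config():
    return SignalConfig()


@pytest.fixture(scope="session")
def small_ga():
    # small search for test tractability; semantics identical
    return GAConfig(population=10, generations=10)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition 20 %MVC trial (two trapezoids)."""
    return generate_trial_bundle(PoolConfig(seed=7), 20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
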