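import pytest

from tpscreen.config import default_config
from tpscreen.simulate import default_simulation_spec, simulate


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def small_run():
    """One small synthetic experiment shared across read-only tests."""
    return simulate(default_simulation_spec(seed=7, n_noise_features=200))
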