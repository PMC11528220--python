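import numpy as np
import pytest

from lfpdyn import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fast session for unit tests (not the default study conditions)."""
    return GeneratorConfig(
        seed=0, n_channels_spk=10, n_channels_lfp=8, n_trials=40
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_session(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
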