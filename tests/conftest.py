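import numpy as np
import pytest

from mslesion.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def ms_slice(default_config):
    return generate_phantom(default_config, "MS", rng_seed=1)


@pytest.fixture(scope="session")
def normal_slice(default_config):
    return generate_phantom(default_config, "normal", rng_seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
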