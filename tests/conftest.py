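import numpy as np
import pytest

from tiersim import (
    NetworkConfig,
    SiphonConfig,
    StimulusConfig,
    reference_config,
    run_ensemble,
)


@pytest.fixture(scope="session")
def net_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def stim_config() -> StimulusConfig:
    return StimulusConfig()


@pytest.fixture(scope="session")
def siphon_config() -> SiphonConfig:
    return reference_config()


@pytest.fixture(scope="session")
def smoke_ensemble(net_config, stim_config):
    """A 200-trial random-input ensemble shared across tests."""
    return run_ensemble(net_config, stim_config, 200, base_seed=7000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
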