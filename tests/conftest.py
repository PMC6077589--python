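import numpy as np
import pytest

from ckdproj.config import load_configuration


@pytest.fixture(scope="session")
def default_config():
    return load_configuration()


@pytest.fixture(scope="session")
def default_result(default_config):
    from ckdproj.projection import run_model

    return run_model(default_config.model_parameters())


@pytest.fixture
def rng():
    return np.random.default_rng(20070101)
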