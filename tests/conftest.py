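import numpy as np
import pytest
from hypothesis import settings

from glycoserum.glycan_core import MassConfig
from glycoserum.library import default_library

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def mass_cfg():
    return MassConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240127)
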