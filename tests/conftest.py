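import numpy as np
import pytest

from sdrscan.config import RunConfig
from sdrscan.simulate import ElementSpec, make_element


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture(scope="session")
def intact_element():
    """One default intact element + truth, shared across tests."""
    return make_element(ElementSpec(), 424242)
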