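import numpy as np
import pytest
from hypothesis import settings

from ppredit.builtin import NAD3_WINDOW, NAD4_WINDOW, PPR56

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def ppr56():
    return PPR56


@pytest.fixture
def nad4_window():
    return NAD4_WINDOW


@pytest.fixture
def nad3_window():
    return NAD3_WINDOW


@pytest.fixture
def rng():
    return np.random.default_rng(20230821)
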