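import numpy as np
import pytest

from gdasim import RateConfig, make_amplicon


@pytest.fixture
def config():
    return RateConfig()


@pytest.fixture
def amplicon28():
    """The 28 kb permissive reference amplicon (confined within E)."""
    return make_amplicon(28.0, permissive=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
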