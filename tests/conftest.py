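import numpy as np
import pytest

from dfunet.assembly import desk_scale_config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A reduced dual-track configuration for 32/64-pixel inputs: the full
    architecture (both tracks, fusion, SA, head) at desk scale."""
    return desk_scale_config(64)
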