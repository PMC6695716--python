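import numpy as np
import pytest

from inducardio.signals import design_lowpass


@pytest.fixture(scope="session")
def lpf20():
    """The pipeline's respiration-extraction filter: order 7, 1 Hz at fs 20."""
    return design_lowpass(7, 1.0, 20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
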