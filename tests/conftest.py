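import numpy as np
import pytest

from jetcryst import pbe


@pytest.fixture
def default_grid() -> pbe.SizeGrid:
    """The production default: 30 classes of 2 um spanning 0-60 um."""
    return pbe.make_grid(0.0, 60e-6, 30)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240109)
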