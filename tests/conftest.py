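import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from isquant.io import TimeLapseStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """Random 5-frame single-channel calibrated stack."""
    data = rng.uniform(0, 100, size=(5, 16, 16))
    return TimeLapseStack(data, ("ch0",), pixel_size=0.16, frame_interval=0.5)
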