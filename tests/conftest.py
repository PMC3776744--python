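import numpy as np
import pytest

from hypoperf.image import ImageVolume
from hypoperf.phantoms import GridSpec


@pytest.fixture
def iso_grid():
    """Fine isotropic grid at the in-plane angiography resolution."""
    return GridSpec((40, 40, 40), (0.137, 0.137, 0.137))


@pytest.fixture
def t2_phantom():
    """64x64x8 T2/S0 map pair spanning the analysis range [20, 150] ms."""
    shape, sp = (64, 64, 8), (0.156, 0.156, 1.0)
    rng = np.random.default_rng(42)
    t2 = ImageVolume(rng.uniform(20.0, 150.0, size=shape), sp)
    s0 = ImageVolume(np.full(shape, 1000.0), sp)
    return t2, s0
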