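import numpy as np
import pytest

from lnatlas import ReferenceGrid


@pytest.fixture
def grid():
    """Default reference grid: 220x220 px at 1 mm, 40 slices of 5 mm."""
    return ReferenceGrid()


@pytest.fixture
def small_grid():
    """Tiny grid for brute-force oracles."""
    return ReferenceGrid(n_x=40, n_y=40, z_min=0.0, z_max=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
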