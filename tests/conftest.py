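import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from vorshealth.grids import LandUseGrid, tessellate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_landuse(rng):
    """12x12 random 6-class cover grid, 1 km cells."""
    return LandUseGrid(rng.integers(1, 7, (12, 12)), cell_size=1.0)


@pytest.fixture
def small_units(small_landuse):
    return tessellate(small_landuse, 3.0)


@pytest.fixture
def random_windows(rng):
    """Small random categorical windows over 2-3 classes for oracle checks."""
    windows = []
    for n_classes in (2, 3):
        for shape in [(2, 2), (3, 3), (4, 4), (5, 5), (6, 6), (3, 5)]:
            for _ in range(3):
                windows.append(rng.integers(1, n_classes + 1, shape))
    return windows
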