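import numpy as np
import pytest

from rmoct.medium_sim import GridSpec, make_phantom
from rmoct.rm_acquisition import ScanGrid, ramp_input_fields


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """32 x 32 field grid at the default physical pitch."""
    return GridSpec(n=32)


@pytest.fixture
def small_scan():
    """7 x 7 scan raster (49 points) fitting the small grid's clear aperture."""
    return ScanGrid(n_side=7, spacing_px=2)


@pytest.fixture
def small_fields(small_scan, small_grid):
    return ramp_input_fields(small_scan, small_grid)


@pytest.fixture
def small_phantom(small_grid):
    return make_phantom(small_grid, depth_smfp=1.5, n_screens=3, seed=7)


@pytest.fixture
def mirror_phantom(small_grid):
    """Zero-depth phantom: a perfect mirror at the surface."""
    return make_phantom(small_grid, depth_smfp=0.0, seed=3)
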