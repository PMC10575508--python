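import numpy as np
import pytest

from corridorscape.raster import RasterGrid
from corridorscape.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cfg():
    """A compact landscape: 3 PAs on a 50x50 grid, two time steps."""
    return SimulationConfig(
        nrows=50,
        ncols=50,
        n_pas=3,
        n_presence=80,
        time_steps=(2000, 2019),
        cropland_target_fraction=(0.07, 0.13),
        seed=7,
    )


def make_grid(values, cellsize=1.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, cellsize=cellsize, origin=(0.0, values.shape[0] * cellsize),
                      nodata=nodata)


@pytest.fixture
def uniform_resistance():
    """10x12 resistance-1 landscape."""
    from corridorscape.connectivity import ResistanceParams, ResistanceSurface

    grid = make_grid(np.ones((10, 12)))
    return ResistanceSurface(grid=grid, params=ResistanceParams())
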