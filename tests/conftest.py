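import numpy as np
import pytest

from isozone.geodata import PlotExtent, PlotGrid


@pytest.fixture
def extent_20x50():
    return PlotExtent(0, 0, 20, 50)


@pytest.fixture
def small_grid():
    """10 x 10 m grid at 1 m resolution."""
    return PlotGrid(PlotExtent(0, 0, 10, 10), 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def scattered_samples(rng):
    """50 random sample points on a 20 x 50 m plot with a smooth trend."""
    x = rng.uniform(0, 20, 50)
    y = rng.uniform(0, 50, 50)
    z = 0.3 * x + 0.1 * y + rng.normal(0, 0.5, 50)
    return x, y, z
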