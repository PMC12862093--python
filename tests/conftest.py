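import numpy as np
import pytest

from smveg.grid import BasinGeometry, RasterGrid


@pytest.fixture
def open_geometry():
    """16x16 grid with no masked cells."""
    return BasinGeometry(16, 16, 20.0)


@pytest.fixture
def masked_geometry():
    """12x12 grid with a masked corner block."""
    mask = np.zeros((12, 12), dtype=bool)
    mask[:4, :4] = True
    return BasinGeometry(12, 12, 20.0, (0.0, 0.0), mask)


def const_grid(geometry, value, name="g"):
    return RasterGrid(np.full(geometry.shape, float(value)), geometry, name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
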