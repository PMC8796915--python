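import numpy as np
import pytest

from bemispread.landscape import Landscape
from bemispread.raster_io import GridSpec, RasterLayer


def homogeneous_landscape(nrows, ncols, k=10_000.0, friction=0.0, cell_km=1.0):
    """A uniform arena: constant carrying capacity and friction."""
    spec = GridSpec(ncols=ncols, nrows=nrows)
    return Landscape(
        K=RasterLayer(spec, np.full((nrows, ncols), float(k))),
        friction=RasterLayer(spec, np.full((nrows, ncols), float(friction))),
        cell_km=cell_km,
        k_max=float(k),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def arena_21():
    return homogeneous_landscape(21, 21)
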