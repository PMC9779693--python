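import numpy as np
import pytest

from esvscape.grid import Grid, LandUseGrid


@pytest.fixture
def checkerboard_lu() -> LandUseGrid:
    """8x8 forest/building checkerboard at 500 m pixels."""
    codes = np.indices((8, 8)).sum(axis=0) % 2 + 1
    return LandUseGrid(codes.astype(np.int16), {1: "forest", 2: "building"}, 500.0)


@pytest.fixture
def ramp_grid() -> Grid:
    """4x4 grid of 1..16 at 100 m pixels."""
    return Grid(np.arange(1, 17, dtype=float).reshape(4, 4), 100.0)


@pytest.fixture
def demo_scenario():
    from esvscape.synthetic import simulate_landscape

    return simulate_landscape(seed=7, shape=(32, 32), cell_size=500.0)
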