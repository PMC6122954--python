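import numpy as np
import pytest

from scenemem.geometry import square_arena
from scenemem.memory import train_context
from scenemem.populations import (
    PlaceCompetition,
    make_place_layout,
    make_polar_grid,
)


@pytest.fixture(scope="session")
def arena():
    return square_arena(100.0)


@pytest.fixture(scope="session")
def grid():
    return make_polar_grid()


@pytest.fixture(scope="session")
def layout(arena):
    return make_place_layout(arena.extent)


@pytest.fixture(scope="session")
def competition(layout):
    return PlaceCompetition(layout)


@pytest.fixture(scope="session")
def trained_weights(arena, layout, grid):
    """Spatial-context attractor for the plain square arena."""
    return train_context(arena, layout, grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
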