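import numpy as np
import pytest

from rotornet.synthetic_movies import (
    IrregularSpec,
    SpiralSpec,
    make_irregular_movie,
    make_spiral_movie,
)


@pytest.fixture(scope="session")
def spiral_movie():
    """Small rotating-spiral fixture shared across tests."""
    return make_spiral_movie(SpiralSpec(grid_n=64, n_frames=600))


@pytest.fixture(scope="session")
def irregular_movie():
    """Matched irregular fixture (same size, frames and on-fraction)."""
    return make_irregular_movie(IrregularSpec(grid_n=64, n_frames=600, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
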