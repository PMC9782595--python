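import numpy as np
import pytest

from cultnet.calcium import EventRaster
from cultnet.culture import (
    generate_aggregated_culture,
    generate_homogeneous_culture,
)


@pytest.fixture(scope="session")
def small_aggregated():
    return generate_aggregated_culture(
        n_aggregates=30, modules=3, p_within=0.8, p_between=0.05, seed=1
    )


@pytest.fixture(scope="session")
def small_homogeneous():
    return generate_homogeneous_culture(grid=12, h=0.7, seed=0)


@pytest.fixture
def volley_raster():
    """Raster with two full-network synchronous volleys at t=5 s and 15 s."""
    bits = np.zeros((10, 1000), dtype=np.uint8)
    bits[:, 250] = 1
    bits[:, 750] = 1
    return EventRaster(bits=bits, fps=50.0)


def random_digraph(n: int, p: float, rng) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)
    return a
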