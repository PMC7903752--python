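import numpy as np
import pytest

from organoidyn import OrganoidState, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def octahedron_state():
    """Six cells on a regular octahedron of radius 20 µm, springs at rest.

    All 12 hull edges have length 20*sqrt(2); with ell0 set to that value the
    spring forces vanish and the state is a mechanical fixed point at zero
    pressure.
    """
    radius = 20.0
    pts = radius * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    return OrganoidState.from_positions(pts, radius=5.0, n=0.0)


@pytest.fixture
def octahedron_params():
    return SimulationParams(ell0=20.0 * np.sqrt(2.0), sigma=0.0, j_in=0.0)


def random_trace(rng, max_len=100):
    """A positive random-walk area trace with occasional jumps and plateaus."""
    n = int(rng.integers(6, max_len + 1))
    steps = rng.normal(0.0, 0.05, size=n)
    jumps = rng.random(n) < 0.1
    steps[jumps] += rng.normal(0.0, 0.3, size=int(jumps.sum()))
    area = 0.1 * np.exp(np.cumsum(steps))
    if rng.random() < 0.3:  # quantise to provoke exact ties
        area = np.round(area, 2) + 0.01
    times = 0.5 * np.arange(n)
    return times, area
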