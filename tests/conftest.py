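import numpy as np
import pytest

from gyroshape import Trajectory, make_template, uniform_grid


@pytest.fixture(scope="session")
def grid200():
    return uniform_grid(200)


@pytest.fixture(scope="session")
def curl_template():
    return make_template("curl", 1.0, 0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smooth_curve_library(grid200):
    """Small library of smooth test curves on the common grid."""
    g = grid200
    return [
        Trajectory(g, 120 * np.sin(2 * np.pi * g) * np.sin(np.pi * g) ** 2),
        Trajectory(g, 80 * np.exp(-((g - 0.4) ** 2) / 0.02)),
        Trajectory(g, 50 * (g - 0.5) ** 3 + 10 * g),
        Trajectory(g, 30 * np.cos(3 * np.pi * g) + 5),
        Trajectory(g, 100 * g * (1 - g) * np.sin(4 * np.pi * g)),
    ]


def random_smooth_curve(rng, grid, amplitude=100.0, n_modes=5):
    """Random band-limited curve; used for isometry/property checks."""
    vals = np.zeros_like(grid)
    for m in range(1, n_modes + 1):
        vals += rng.normal(0, 1.0 / m) * np.sin(np.pi * m * grid + rng.uniform(0, 2 * np.pi))
    return Trajectory(grid, amplitude * vals)
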