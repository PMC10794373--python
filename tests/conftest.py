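import numpy as np
import pandas as pd
import pytest

from vrepm import MazeGeometry, SessionMeta, Trajectory, make_default_geometry


@pytest.fixture(scope="session")
def geom() -> MazeGeometry:
    return make_default_geometry()


def make_trajectory(xz, rate=5.0, task_duration=None, participant="T", exposure=1):
    """Build a uniform-rate trajectory from an (n, 2) list of (x, z) points."""
    xz = np.asarray(xz, dtype=float)
    n = len(xz)
    dt = 1.0 / rate
    data = pd.DataFrame(
        {
            "t": dt * np.arange(n),
            "x": xz[:, 0],
            "y": np.full(n, 165.0),
            "z": xz[:, 1],
            "rx": np.zeros(n),
            "ry": np.zeros(n),
            "rz": np.zeros(n),
        }
    )
    meta = SessionMeta(
        participant, exposure=exposure, task_duration=task_duration or n * dt
    )
    return Trajectory(data, meta, sample_rate=rate)


def random_trajectory(rng, n=1500, rate=5.0, scale=175.0):
    """Unconstrained random walk over the maze bounding box."""
    steps = rng.normal(0.0, 12.0, (n, 2))
    xz = np.clip(np.cumsum(steps, axis=0), -scale, scale)
    return make_trajectory(xz, rate=rate)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
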