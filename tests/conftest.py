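import numpy as np
import pytest

import sptkit as sk


@pytest.fixture(scope="session")
def calibration():
    """RD null-band calibration at the standard conditions (shared, seeded)."""
    return sk.calibrate_cutoffs(seed=42)


@pytest.fixture
def brownian_300():
    """200 noise-free Brownian tracks, D=0.1 um^2/s, 300 frames, dt=0.1 s."""
    cfg = sk.SimConfig(n_tracks=200, n_steps=300, dt=0.1, D=0.1, seed=7)
    return sk.simulate_brownian(cfg)


@pytest.fixture
def square_track():
    """Deterministic 4-point track tracing the unit square."""
    return sk.Trajectory("sq", [0, 1, 2, 3], [0.0, 1.0, 1.0, 0.0],
                         [0.0, 0.0, 1.0, 1.0], dt=0.1)


def random_track(rng, n=60, dt=0.1, scale=0.1, track_id="r"):
    steps = rng.normal(0.0, scale, size=(n - 1, 2))
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return sk.Trajectory(track_id, np.arange(n), pos[:, 0], pos[:, 1], dt=dt)
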