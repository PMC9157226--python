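import numpy as np
import pytest

from inclinefield import ArenaSpec, Trajectory


def make_traj(
    x,
    y,
    valid=None,
    frame_rate=25.0,
    arena=None,
    subject_id="t0",
    species="synthetic",
):
    """Build a trajectory from coordinate lists at a fixed frame rate."""
    x = np.asarray(x, dtype=float)
    if arena is None:
        arena = ArenaSpec(frame_rate=frame_rate)
    t = np.arange(len(x)) / arena.frame_rate
    return Trajectory(
        subject_id=subject_id,
        species=species,
        arena=arena,
        t=t,
        x=x,
        y=np.asarray(y, dtype=float),
        valid=valid,
    )


@pytest.fixture
def straight_up():
    """x fixed, y climbing 20 -> 90 in 1 cm steps: pure up-slope travel."""
    y = np.arange(20.0, 91.0)
    return make_traj(np.full_like(y, 50.0), y)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_walk_traj(rng, n=200, arena=None, valid=None):
    """Small bounded random walk for property tests."""
    if arena is None:
        arena = ArenaSpec()
    steps = rng.normal(0.0, 1.0, size=(n, 2))
    pos = np.clip(50.0 + np.cumsum(steps, axis=0), 0.0, 100.0)
    return make_traj(pos[:, 0], pos[:, 1], valid=valid, arena=arena)
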