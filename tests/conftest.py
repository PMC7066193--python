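import numpy as np
import pytest

from flylat.track_data import ArenaConfig, Track


def make_track(
    x,
    y,
    fly_id="fly",
    heading=None,
    wing_left=None,
    wing_right=None,
    frame=None,
    fps=10.0,
):
    """Build a Track from coordinate lists, defaulting the other channels."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if frame is None:
        frame = np.arange(n)
    frame = np.asarray(frame)
    return Track(
        fly_id=fly_id,
        frame=frame,
        t=frame / fps,
        x=x,
        y=np.asarray(y, dtype=float),
        heading=np.zeros(n) if heading is None else np.asarray(heading, dtype=float),
        wing_left=np.zeros(n) if wing_left is None else np.asarray(wing_left, dtype=float),
        wing_right=np.zeros(n) if wing_right is None else np.asarray(wing_right, dtype=float),
    )


def mirror_track(track: Track) -> Track:
    """Reflect a track about the x axis and swap the wing labels.

    This is the physical mirror image of the behavior: every anticlockwise
    turn becomes clockwise, the partner side flips, and the fly's left wing
    becomes its right.
    """
    return Track(
        fly_id=track.fly_id + "_mirror",
        frame=track.frame.copy(),
        t=track.t.copy(),
        x=track.x.copy(),
        y=-track.y,
        heading=np.mod(-track.heading, 360.0),
        wing_left=track.wing_right.copy(),
        wing_right=track.wing_left.copy(),
    )


def random_walk_track(rng, n=20, fly_id="rw", scale=1.0) -> Track:
    """Random in-plane walk with random headings and wing angles."""
    steps = rng.normal(0, scale, size=(n, 2))
    pos = np.cumsum(steps, axis=0)
    return make_track(
        pos[:, 0],
        pos[:, 1],
        fly_id=fly_id,
        heading=rng.uniform(0, 360, n),
        wing_left=rng.uniform(0, 90, n),
        wing_right=rng.uniform(0, 90, n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def short_arena():
    return ArenaConfig(duration=60.0)


@pytest.fixture(scope="session")
def small_experiment():
    """A small mixed-design simulated experiment shared across tests."""
    from flylat.synthetic_flies import SimConfig, simulate_experiment

    cfg = SimConfig(seed=17, arena=ArenaConfig(duration=60.0))
    design = {
        "RAL-69": {"F": 3, "M": 3, "FF": 4, "MM": 4, "FM": 4},
        "RAL-136": {"F": 3, "M": 3, "FF": 4, "MM": 4, "FM": 4},
    }
    return simulate_experiment(design, cfg)
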