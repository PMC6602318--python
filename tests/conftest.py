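import numpy as np
import pytest

from circafish.circadian import LightSchedule
from circafish.tracker import Trajectory
from circafish.video_io import FrameSequence, TankLayout, TankROI


def make_traj(points, fps=30.0, fish_id=0, tank_id=0):
    """Trajectory from a list of (x, y) cm points."""
    return Trajectory(
        fish_id=fish_id,
        tank_id=tank_id,
        positions=np.asarray(points, dtype=float),
        fps=fps,
        units="cm",
    )


@pytest.fixture
def small_layout():
    """Two 30x20 px tanks side by side, 2 px/cm."""
    return TankLayout(
        tanks=[
            TankROI(tank_id=0, x_min=2, y_min=2, x_max=32, y_max=22, expected_fish=1),
            TankROI(tank_id=1, x_min=36, y_min=2, x_max=66, y_max=22, expected_fish=1),
        ],
        px_per_cm=2.0,
    )


@pytest.fixture
def schedule():
    return LightSchedule(lights_on_hour=8.0, lights_off_hour=20.0)


@pytest.fixture
def static_seq():
    rng = np.random.default_rng(42)
    frame = rng.integers(0, 256, (24, 70), dtype=np.uint8)
    return FrameSequence(np.repeat(frame[None], 10, axis=0), fps=30.0)
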