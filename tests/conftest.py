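import numpy as np
import pytest

from gazewalk.design import Configuration
from gazewalk.geometry import CameraModel, RoomLayout, place_cups
from gazewalk.simulate import (
    GazeScript,
    NoiseModel,
    WalkerProfile,
    default_script,
    simulate_trial,
)


@pytest.fixture(scope="session")
def layout():
    return RoomLayout()


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def config_lrrr():
    return Configuration("left", "right", "right", "right")


@pytest.fixture(scope="session")
def placements_lrrr(config_lrrr, layout):
    return place_cups(config_lrrr, layout)


def script_no_blinks() -> GazeScript:
    s = default_script()
    return GazeScript(segments=s.segments, blink_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_trial(config_lrrr):
    """One fully noiseless trial (no gaze noise, no blinks, no detection
    dropouts/false positives) shared across tests."""
    return simulate_trial(config_lrrr, script=script_no_blinks(),
                          noise=NoiseModel.noiseless(), seed=11)


@pytest.fixture(scope="session")
def noisy_trial(config_lrrr):
    """One trial under the default (study-condition) noise model."""
    return simulate_trial(config_lrrr, seed=11)


def random_pose_params(rng, layout: RoomLayout):
    """A random feasible observer state (x, y, eye height, yaw, pitch)
    looking roughly toward the table so most cups are in view."""
    x = rng.uniform(-layout.room_width / 2 + 40, layout.room_width / 2 - 40)
    y = rng.uniform(-250.0, layout.floor_obstacle_depths[0])
    eye_h = rng.uniform(149.0, 182.0)
    blue_y = layout.door_to_table + layout.target_depth_on_table
    yaw = np.rad2deg(np.arctan2(-x, blue_y - y)) + rng.uniform(-8, 8)
    pitch = rng.uniform(-30.0, -5.0)
    return x, y, eye_h, yaw, pitch
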