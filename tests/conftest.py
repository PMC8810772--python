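"""Shared fixtures: small simulated rigs that run in seconds.

The physical defaults (whole 55 mm plate on a 2592 x 1944 macro sensor,
full-size micro sensor) are too large for fast unit tests, so tests use a
small plate rendered at the same pixel scales with proportionally smaller
sensors and short worms that fit entirely in the micro crop.  Segmentation
gates are configured to the rendered worm size, exactly as they would be
tuned on a real rig.
"""

from __future__ import annotations

import numpy as np
import pytest

from wormrig import macrotracking as mt
from wormrig import robot_model as rm
from wormrig import scene_sim as sim
from wormrig import tracking_controller as tc


SMALL_PLATE_RADIUS = 5.0  # mm
SMALL_BODY_LENGTH = 0.1  # mm; fits the 512 px micro crop with margin


def make_small_scene(models, n_per_model, duration, seed,
                     plate_radius=SMALL_PLATE_RADIUS,
                     body_length=SMALL_BODY_LENGTH, dt=0.5):
    scene = sim.simulate_trajectories(models, n_per_model,
                                      duration=duration, dt=dt, seed=seed,
                                      plate_radius=plate_radius)
    for worm in scene.worms:
        worm.body_length = body_length
    return scene


@pytest.fixture
def macro_cam():
    return sim.macro_camera((400, 400))


@pytest.fixture
def micro_cam():
    return sim.micro_camera((512, 512), defocus_gain=0.05)


@pytest.fixture
def step_model(macro_cam, micro_cam):
    return rm.step_model_from_cameras(macro_cam, micro_cam)


@pytest.fixture
def seg_params():
    # min_area sized for the 0.1 mm test worms (~17 px^2 at 27.31 um/pxl)
    return mt.SegmentationParams(window=25, offset=15.0, min_area=8,
                                 max_area=600, max_jump=60.0)


@pytest.fixture
def controller_config(macro_cam, micro_cam, step_model, seg_params):
    return tc.ControllerConfig(macro_camera=macro_cam, micro_camera=micro_cam,
                               step_model=step_model, seg_params=seg_params)


def constant_speed_trajectory(worm_id=0, speed_um_s=200.0, duration=60.0,
                              dt=0.5, radius_mm=2.0,
                              body_length=SMALL_BODY_LENGTH):
    """Circular constant-speed path (bounded velocity, unlike the PRW)."""
    n = int(round(duration / dt)) + 1
    omega = speed_um_s * 1e-3 / radius_mm  # rad/s
    t = np.arange(n) * dt
    positions = np.stack([radius_mm * np.cos(omega * t),
                          radius_mm * np.sin(omega * t)], axis=1)
    headings = omega * t + np.pi / 2
    return sim.WormTrajectory(worm_id=worm_id, positions=positions,
                              headings=headings, body_length=body_length,
                              strain="circular")
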