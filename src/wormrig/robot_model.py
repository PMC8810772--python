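"""Virtual Cartesian robot: step kinematics, laser projection and parallax.

The physical rig moves a carriage on X/Y and a camera head on Z with stepper
motors.  This module models exactly what the controller needs:

* the pixel-to-step conversion ("the error is multiplied by the pixel/step
  ratio"), a linear model with rounding to whole steps;
* the ground-truth projection of the head-mounted laser into the macro
  image, used for goal acquisition;
* trapezoidal-profile motion timing under the rig's velocity and
  acceleration limits (v_max = 8000 stp/s, a_max = 25000 stp/s^2);
* the parallax error of the fixed-camera step model, dx = dz * tan(alpha),
  caused by agar-height variation under a camera with half field of view
  alpha = 20.7 deg.

Step axes follow the image convention (x steps = columns, y steps = rows,
y increasing downwards); see `wormrig.scene_sim` for the full frame
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import InvalidParameterError, TravelLimitError
from .scene_sim import CameraModel, PlateScene

__all__ = [
    "RobotState",
    "StepModel",
    "GeometryModel",
    "STEP_SIZE_MM",
    "project_laser",
    "pixels_to_steps",
    "parallax_error",
    "move_carriage",
    "step_model_from_cameras",
]

#: World displacement per motor step, mm (1.09 um/step, the unit the
#: module-index histograms are reported in).
STEP_SIZE_MM = 1.09e-3


@dataclass(frozen=True)
class RobotState:
    """Carriage/head pose in motor steps plus laser state."""

    carriage: tuple[int, int] = (0, 0)  # (x, y) steps
    head_z: int = 0  # steps
    laser_on: bool = False

    def head_world(self, step_size_mm: float = STEP_SIZE_MM) -> tuple[float, float]:
        """World (x, y) mm of the head axis; y steps point down (image frame)."""
        return (self.carriage[0] * step_size_mm,
                -self.carriage[1] * step_size_mm)


@dataclass(frozen=True)
class StepModel:
    """Linear pixel-to-step conversion plus motion limits.

    ``macro_steps_per_pixel`` and ``micro_steps_per_pixel`` are the constants
    the controller multiplies a pixel error by to obtain a step command.
    They need not match the true rig geometry exactly: the proportional loop
    tolerates (and the tests exercise) mis-scaled models.
    """

    macro_steps_per_pixel: float
    micro_steps_per_pixel: float
    v_max: float = 8000.0  # stp/s
    a_max: float = 25000.0  # stp/s^2
    step_size_mm: float = STEP_SIZE_MM

    def __post_init__(self) -> None:
        for name in ("macro_steps_per_pixel", "micro_steps_per_pixel",
                     "v_max", "a_max", "step_size_mm"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


def step_model_from_cameras(macro: CameraModel, micro: CameraModel,
                            step_size_mm: float = STEP_SIZE_MM,
                            scale_error: float = 1.0,
                            v_max: float = 8000.0,
                            a_max: float = 25000.0) -> StepModel:
    """Derive the conversion constants from the simulated camera geometry.

    ``scale_error`` multiplies both ratios to emulate an imperfectly
    calibrated model (e.g. 0.8 for a 20% under-scaled one).
    """
    return StepModel(
        macro_steps_per_pixel=scale_error * macro.scale_mm / step_size_mm,
        micro_steps_per_pixel=scale_error * micro.scale_mm / step_size_mm,
        v_max=v_max, a_max=a_max, step_size_mm=step_size_mm)


@dataclass(frozen=True)
class GeometryModel:
    """Optical geometry of the macro view for the parallax model."""

    alpha: float = math.radians(41.41 / 2.0)  # half field of view, rad
    agar_dz: float = 1.0  # typical agar height variation, mm

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < math.pi / 2:
            raise InvalidParameterError("alpha must be in (0, pi/2)")


def project_laser(state: RobotState, scene: PlateScene,
                  camera: CameraModel) -> Optional[np.ndarray]:
    """Ground-truth macro pixel position of the agar-surface laser spot.

    Returns ``None`` when the laser is off.  This is the exact inverse of
    the configured step geometry; the controller never reads it directly
    but detects the rendered spot in the frame.
    """
    if not state.laser_on:
        return None
    return camera.world_to_pixel(np.array(state.head_world()))


def pixels_to_steps(error, model: StepModel, which: str = "macro") -> np.ndarray:
    """Convert a pixel error to a whole-step command.

    steps = round(error * steps_per_pixel), rounding half away from zero.
    """
    if which not in ("macro", "micro"):
        raise InvalidParameterError(f"unknown camera kind {which!r}")
    spp = (model.macro_steps_per_pixel if which == "macro"
           else model.micro_steps_per_pixel)
    raw = np.asarray(error, dtype=float) * spp
    return np.copysign(np.floor(np.abs(raw) + 0.5), raw).astype(int)


def parallax_error(dz: float, geometry: GeometryModel) -> float:
    """Lateral position error (mm) induced by a height offset ``dz`` mm."""
    return dz * math.tan(geometry.alpha)


def move_carriage(state: RobotState, dsteps: tuple[int, int],
                  model: StepModel,
                  travel_limits: Optional[tuple[int, int]] = None
                  ) -> tuple[RobotState, float]:
    """Apply a relative XY step command; return the new state and move time.

    Timing uses a trapezoidal velocity profile per axis under
    ``v_max``/``a_max`` (triangular for short moves, d <= v^2/a); the two
    axes move concurrently so the duration is the slower axis's time.
    """
    new_xy = (state.carriage[0] + int(dsteps[0]),
              state.carriage[1] + int(dsteps[1]))
    if travel_limits is not None:
        lim_x, lim_y = travel_limits
        if abs(new_xy[0]) > lim_x or abs(new_xy[1]) > lim_y:
            raise TravelLimitError(
                f"target {new_xy} exceeds travel limits {travel_limits}")
    duration = max(_axis_time(abs(int(d)), model.v_max, model.a_max)
                   for d in dsteps)
    return replace(state, carriage=new_xy), duration


def _axis_time(d: float, v: float, a: float) -> float:
    if d == 0:
        return 0.0
    if d <= v * v / a:  # never reaches v_max: triangular profile
        return 2.0 * math.sqrt(d / a)
    return d / v + v / a
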