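"""State machine driving the mechanical (micro) tracking of one worm at a time.

While software macrotracking runs constantly on the 1 fps whole-plate
sequence, the machine cycles through:

    MACROTRACK -> SELECT -> GOAL_ACQUISITION -> MICROTRACK -> FOCUS
        -> CAPTURE -> MACROTRACK -> ...

* SELECT picks the lowest-id live worm not yet captured.
* GOAL_ACQUISITION turns the laser on, measures the pixel error between the
  detected laser spot and the worm centroid in the macro image, converts it
  to steps and moves the carriage; when the error drops below 15 px the
  worm is framed by the micro camera and the laser is switched off.
* MICROTRACK servoes the worm centroid to the micro image centre.
* FOCUS sweeps Z and keeps the sharpest plane (mean squared gradient).
* CAPTURE records a 30 s micro sequence at 2 fps (60 frames) while the
  servo keeps running; the commanded x/y step shifts at each instant k are
  the control actions the displacement-module index is computed from.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import macrotracking as mt
from . import robot_model as rm
from . import scene_sim as sim
from .errors import (AcquisitionError, FocusFailureError,
                     InvalidParameterError, LostTargetError)

__all__ = [
    "MachineState",
    "ALLOWED_TRANSITIONS",
    "CaptureSchedule",
    "SessionLog",
    "select_next_worm",
    "goal_acquisition_step",
    "microtrack_step",
    "autofocus",
    "detect_laser",
    "run_session",
]

#: Pixel error below which goal acquisition hands over to microtracking.
ACQUISITION_ERROR_PX = 15.0


class MachineState(enum.Enum):
    MACROTRACK = "MACROTRACK"
    SELECT = "SELECT"
    GOAL_ACQUISITION = "GOAL_ACQUISITION"
    MICROTRACK = "MICROTRACK"
    FOCUS = "FOCUS"
    CAPTURE = "CAPTURE"


#: Edges of the state graph.  MACROTRACK is logically concurrent; entering
#: it here means "no worm is being mechanically tracked right now".
ALLOWED_TRANSITIONS: dict[MachineState, set[MachineState]] = {
    MachineState.MACROTRACK: {MachineState.SELECT},
    MachineState.SELECT: {MachineState.GOAL_ACQUISITION,
                          MachineState.MACROTRACK},
    MachineState.GOAL_ACQUISITION: {MachineState.MICROTRACK,
                                    MachineState.SELECT},
    MachineState.MICROTRACK: {MachineState.FOCUS,
                              MachineState.GOAL_ACQUISITION},
    MachineState.FOCUS: {MachineState.CAPTURE,
                         MachineState.GOAL_ACQUISITION},
    MachineState.CAPTURE: {MachineState.MACROTRACK,
                           MachineState.GOAL_ACQUISITION},
}


@dataclass(frozen=True)
class CaptureSchedule:
    """Acquisition rates: 1 fps macro, 2 fps micro for 30 s (60 images)."""

    macro_rate: float = 1.0  # fps
    micro_rate: float = 2.0  # fps
    micro_duration: float = 30.0  # s

    def __post_init__(self) -> None:
        if self.macro_rate <= 0 or self.micro_rate <= 0 or self.micro_duration <= 0:
            raise InvalidParameterError("rates and duration must be > 0")

    @property
    def frames_per_worm(self) -> int:
        return int(round(self.micro_rate * self.micro_duration))


@dataclass
class SessionLog:
    """Control actions and state trace of one plate session."""

    actions: list[dict] = field(default_factory=list)  # worm_id, k, t, dx, dy, state
    state_trace: list[tuple[float, MachineState]] = field(default_factory=list)
    capture_times: dict[int, list[float]] = field(default_factory=dict)
    skipped: list[int] = field(default_factory=list)

    def log_state(self, t: float, state: MachineState) -> None:
        if self.state_trace and self.state_trace[-1][1] is state:
            return
        self.state_trace.append((t, state))

    def log_action(self, worm_id: int, k: int, t: float, dx: int, dy: int,
                   state: MachineState) -> None:
        self.actions.append({"worm_id": worm_id, "k": k, "t": t,
                             "dx_steps": int(dx), "dy_steps": int(dy),
                             "state": state.value})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.actions, columns=["worm_id", "k", "t",
                                                   "dx_steps", "dy_steps",
                                                   "state"])

    def actions_for(self, worm_id: int, states=("CAPTURE",)) -> np.ndarray:
        rows = [(a["dx_steps"], a["dy_steps"]) for a in self.actions
                if a["worm_id"] == worm_id and a["state"] in states]
        return np.array(rows, dtype=float).reshape(-1, 2)


def select_next_worm(table: mt.TrackTable) -> Optional[int]:
    """Lowest-id live (non-censored) worm not yet captured, else None."""
    for wid in table.active_ids:
        if wid not in table.tested_set:
            return wid
    return None


def goal_acquisition_step(laser_pxl, worm_pxl, model: rm.StepModel
                          ) -> tuple[np.ndarray, float]:
    """One proportional correction driving the laser spot onto the worm.

    Returns the step command and the current pixel error magnitude; the
    caller keeps iterating until the error is below 15 px.
    """
    laser = np.asarray(laser_pxl, dtype=float)
    worm = np.asarray(worm_pxl, dtype=float)
    err_vec = worm - laser
    command = rm.pixels_to_steps(err_vec, model, which="macro")
    return command, float(np.hypot(*err_vec))


def detect_laser(frame: sim.Frame, threshold: float = 250.0
                 ) -> np.ndarray:
    """Centroid (x, y) of the saturated laser spot in a macro frame."""
    mask = frame.pixels >= threshold
    if not mask.any():
        raise AcquisitionError("laser spot not detected in macro frame")
    rr, cc = np.nonzero(mask)
    return np.array([cc.mean(), rr.mean()])


def microtrack_step(frame: sim.Frame, model: rm.StepModel,
                    params: Optional[mt.SegmentationParams] = None
                    ) -> np.ndarray:
    """Step command centring the worm centroid in the micro image.

    The worm occupies a large part of the frame, so a plain adaptive
    segmentation of the darkest blob suffices; its centroid is servoed to
    the image centre.  Raises LostTargetError when nothing worm-like is
    visible, which sends the machine back to goal acquisition.
    """
    if params is None:
        params = mt.SegmentationParams(window=51, offset=10.0, min_area=50,
                                       max_area=10 ** 9)
    mask = mt.segment_adaptive(frame, params)
    detections = mt.classify_by_size(mask, params, frame_t=frame.t)
    if not detections:
        raise LostTargetError("no worm found in micro frame")
    target = max(detections, key=lambda d: d.area)
    rows, cols = frame.pixels.shape
    centre = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    err_vec = np.asarray(target.centroid) - centre
    return rm.pixels_to_steps(err_vec, model, which="micro")


def autofocus(z_candidates: list[int],
              capture: Callable[[int], sim.Frame]) -> int:
    """Return the candidate Z maximizing mean squared intensity gradient."""
    if len(z_candidates) < 2:
        raise InvalidParameterError("need at least 2 focus candidates")
    best_z, best_score = None, 0.0
    for z in z_candidates:
        img = np.asarray(capture(z).pixels, dtype=float)
        gy, gx = np.gradient(img)
        score = float(np.mean(gx ** 2 + gy ** 2))
        if score > best_score:
            best_z, best_score = z, score
    if best_z is None or best_score <= 1e-12:
        raise FocusFailureError("all candidate frames are featureless")
    return best_z


# ---------------------------------------------------------------------------
# Full session loop
# ---------------------------------------------------------------------------

@dataclass
class ControllerConfig:
    """Everything run_session needs besides the scene itself."""

    macro_camera: sim.CameraModel
    micro_camera: sim.CameraModel
    step_model: rm.StepModel
    schedule: CaptureSchedule = field(default_factory=CaptureSchedule)
    seg_params: mt.SegmentationParams = field(
        default_factory=mt.SegmentationParams)
    micro_seg_params: Optional[mt.SegmentationParams] = None
    acquisition_error_px: float = ACQUISITION_ERROR_PX
    acquisition_retries: int = 5
    track_max_misses: int = 3  # coast frames before censoring an identity
    laser_mask_px: float = 18.0  # blanked radius around the detected laser
    focus_span: int = 40  # steps swept either side of the current Z
    focus_points: int = 9
    store_frames: bool = True
    backlight: float = sim.DEFAULT_BACKLIGHT


def run_session(scene: sim.PlateScene, config: ControllerConfig
                ) -> tuple[SessionLog, mt.TrackTable, dict[int, list[sim.Frame]]]:
    """Run the full plate session: visit every live worm once.

    Time advances at the micro tick (1 / micro_rate); macro frames are
    rendered and processed at macro_rate throughout.  Each selected worm
    gets laser-guided goal acquisition, one focus sweep and a capture
    sequence of exactly ``schedule.frames_per_worm`` micro frames with the
    control actions logged at each instant k.  Worms whose acquisition
    repeatedly fails are skipped and flagged; the session ends when every
    worm is tested or the scene runs out of time.
    """
    sched = config.schedule
    dt = 1.0 / sched.micro_rate
    macro_every = max(1, int(round(1.0 / (sched.macro_rate * dt))))
    log = SessionLog()
    table = mt.TrackTable()
    frames: dict[int, list[sim.Frame]] = {}
    robot = rm.RobotState(laser_on=False,
                          head_z=int(config.micro_camera.focus_z) + 25)
    state = MachineState.MACROTRACK
    log.log_state(0.0, state)
    current: Optional[int] = None
    retries = 0
    captured = 0
    k_instant = 0
    n_ticks = int(round(scene.duration / dt))

    def process_macro(t: float, laser_px=None) -> None:
        frame = sim.render_macro_frame(scene, t, backlight=config.backlight,
                                       laser_spot=laser_px,
                                       camera=config.macro_camera)
        mask = mt.segment_adaptive(frame, config.seg_params)
        dets = mt.classify_by_size(mask, config.seg_params, frame_t=t)
        table.update(dets, t, config.seg_params.max_jump,
                     max_misses=config.track_max_misses)

    for tick in range(n_ticks + 1):
        t = tick * dt
        if tick % macro_every == 0 and state not in (
                MachineState.GOAL_ACQUISITION,):
            process_macro(t)

        if state is MachineState.MACROTRACK:
            state = _goto(log, t, state, MachineState.SELECT)

        if state is MachineState.SELECT:
            current = select_next_worm(table)
            if current is None:
                log.log_state(t, MachineState.MACROTRACK)
                state = MachineState.MACROTRACK
                if all(w in table.tested_set or w in table.censored
                       for w in table.tracks) and table.tracks:
                    break
                continue
            retries = 0
            robot = rm.RobotState(carriage=robot.carriage,
                                  head_z=robot.head_z, laser_on=True)
            state = _goto(log, t, state, MachineState.GOAL_ACQUISITION)
            continue

        if state is MachineState.GOAL_ACQUISITION:
            laser_truth = rm.project_laser(robot, scene, config.macro_camera)
            frame = sim.render_macro_frame(scene, t,
                                           backlight=config.backlight,
                                           laser_spot=tuple(laser_truth),
                                           camera=config.macro_camera)
            try:
                laser_px = detect_laser(frame)
                # blank the saturated spot before segmenting, else its halo
                # under the local-mean threshold yields spurious blobs
                rows, cols = frame.pixels.shape
                yy, xx = np.ogrid[0:rows, 0:cols]
                near = (np.hypot(xx - laser_px[0], yy - laser_px[1])
                        <= config.laser_mask_px)
                clean = sim.Frame(np.where(near, config.backlight,
                                           frame.pixels), t,
                                  frame.camera, "macro")
                mask = mt.segment_adaptive(clean, config.seg_params)
                dets = mt.classify_by_size(mask, config.seg_params, frame_t=t)
                table.update(dets, t, config.seg_params.max_jump,
                             max_misses=config.track_max_misses)
                if current not in table.tracks or current in table.censored:
                    raise AcquisitionError("selected worm lost")
                worm_px = table.last_position(current)
                command, err = goal_acquisition_step(laser_px, worm_px,
                                                     config.step_model)
                if err < config.acquisition_error_px:
                    robot = rm.RobotState(carriage=robot.carriage,
                                          head_z=robot.head_z,
                                          laser_on=False)
                    state = _goto(log, t, state, MachineState.MICROTRACK)
                    continue
                robot, _ = rm.move_carriage(robot, tuple(command),
                                            config.step_model)
                retries += 1
                if retries > config.acquisition_retries:
                    raise AcquisitionError("acquisition retry limit")
            except AcquisitionError:
                log.skipped.append(current)
                table.mark_tested(current)
                robot = rm.RobotState(carriage=robot.carriage,
                                      head_z=robot.head_z, laser_on=False)
                state = _goto(log, t, state, MachineState.SELECT)
            continue

        if state is MachineState.MICROTRACK:
            try:
                robot = _servo_micro(scene, t, robot, config, log,
                                     current, None)
            except LostTargetError:
                retries = 0
                robot = rm.RobotState(carriage=robot.carriage,
                                      head_z=robot.head_z, laser_on=True)
                state = _goto(log, t, state, MachineState.GOAL_ACQUISITION)
                continue
            state = _goto(log, t, state, MachineState.FOCUS)
            continue

        if state is MachineState.FOCUS:
            # microtracking keeps running while the focus sweep executes
            try:
                robot = _servo_micro(scene, t, robot, config, log,
                                     current, None)
            except LostTargetError:
                retries = 0
                robot = rm.RobotState(carriage=robot.carriage,
                                      head_z=robot.head_z, laser_on=True)
                state = _goto(log, t, state, MachineState.GOAL_ACQUISITION)
                continue
            span, npts = config.focus_span, config.focus_points
            zs = [int(robot.head_z + s) for s in
                  np.linspace(-span, span, npts)]
            head_world = robot.head_world(config.step_model.step_size_mm)
            best = autofocus(zs, lambda z: sim.render_micro_frame(
                scene, t, head_world, z, camera=config.micro_camera,
                backlight=config.backlight))
            robot = rm.RobotState(carriage=robot.carriage, head_z=best,
                                  laser_on=False)
            captured = 0
            k_instant = 0
            frames[current] = []
            log.capture_times[current] = []
            state = _goto(log, t, state, MachineState.CAPTURE)
            continue

        if state is MachineState.CAPTURE:
            try:
                robot = _servo_micro(scene, t, robot, config, log,
                                     current, k_instant,
                                     store=frames[current])
            except LostTargetError:
                retries = 0
                robot = rm.RobotState(carriage=robot.carriage,
                                      head_z=robot.head_z, laser_on=True)
                state = _goto(log, t, state, MachineState.GOAL_ACQUISITION)
                continue
            log.capture_times[current].append(t)
            captured += 1
            k_instant += 1
            if captured >= sched.frames_per_worm:
                table.mark_tested(current)
                current = None
                state = _goto(log, t, state, MachineState.MACROTRACK)
            continue

    return log, table, frames


def _goto(log: SessionLog, t: float, state: MachineState,
          new: MachineState) -> MachineState:
    if new not in ALLOWED_TRANSITIONS[state]:
        raise RuntimeError(f"illegal transition {state} -> {new}")
    log.log_state(t, new)
    return new


def _servo_micro(scene: sim.PlateScene, t: float, robot: rm.RobotState,
                 config: ControllerConfig, log: SessionLog,
                 worm_id: int, k_instant: Optional[int],
                 store: Optional[list] = None) -> rm.RobotState:
    """Render a micro frame, compute and apply the centring command."""
    head_world = robot.head_world(config.step_model.step_size_mm)
    frame = sim.render_micro_frame(scene, t, head_world, robot.head_z,
                                   camera=config.micro_camera,
                                   backlight=config.backlight)
    command = microtrack_step(frame, config.step_model,
                              params=config.micro_seg_params)
    robot, _ = rm.move_carriage(robot, tuple(command), config.step_model)
    if k_instant is not None:
        log.log_action(worm_id, k_instant, t, command[0], command[1],
                       MachineState.CAPTURE)
        if store is not None and config.store_frames:
            store.append(frame)
    return robot
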