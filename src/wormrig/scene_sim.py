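"""Synthetic plate scenes: worm trajectories and rendered macro/micro frames.

This module stands in for the physical Petri plates and cameras.  Worms move
on a 55 mm dish as persistent random walks parameterized per strain, and the
two camera views of the rig are rendered from the ground-truth trajectories:

* the *macro* view images the whole plate through the beamsplitter at
  27.31 um/pxl on a 2592 x 1944 sensor;
* the *micro* view is a high-magnification crop (1.09 um/pxl) centred on the
  robot head, with defocus blur growing linearly with the head's distance
  from the in-focus Z position.

Coordinate conventions (used package-wide, documented only here):

* **World frame** -- origin at the plate centre, x to the right, y up,
  units mm.
* **Pixel frame** -- origin at the top-left corner, 0-based, ``x`` is the
  column index and ``y`` the row index.  Row index increases *downwards*,
  so ``row = centre_row - y_mm / scale_mm`` and
  ``col = centre_col + x_mm / scale_mm``.
* **Motor steps** -- the carriage X axis is aligned with pixel columns and
  the Y axis with pixel rows (y steps increase downwards, matching the
  image).  One step moves the head ``step_size_mm`` millimetres.

Worms are rendered as dark oriented capsules (thick segments) on the bright
backlit field; body posture (undulation) is deliberately not modelled since
the motility index depends only on centroid motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian

from .errors import InvalidParameterError

__all__ = [
    "StrainMotilityModel",
    "WormTrajectory",
    "PlateScene",
    "CameraModel",
    "Frame",
    "WT_LIKE",
    "MILD_DEFICIT",
    "SEVERE_UNCOORDINATED",
    "STRAIN_PRESETS",
    "simulate_trajectories",
    "render_macro_frame",
    "render_micro_frame",
    "macro_camera",
    "micro_camera",
]

#: Default plate radius, mm ("standard dishes measuring 55 mm").
PLATE_RADIUS_MM = 27.5

#: Grey level of the uniform backlight when no lighting state is supplied.
DEFAULT_BACKLIGHT = 180.0

#: How much darker than the backlight a worm silhouette renders.
DEFAULT_WORM_CONTRAST = 60.0


@dataclass(frozen=True)
class StrainMotilityModel:
    """Synthetic motility parameters for one strain.

    The real strains assayed on the rig (wild type N2, a CAG-expansion
    transgenic with a mild deficit, and severely uncoordinated unc mutants)
    differ in crawl speed and in how often they stall; this model captures
    exactly those two axes plus directional persistence.

    Parameters
    ----------
    name:
        Strain label carried through to the metrics reports.
    speed_scale:
        Mean crawl speed, um/s.  Per-step speeds are drawn from an
        exponential distribution with this mean, so individual instants
        range from near-stationary to bursts.
    pause_prob:
        Probability per time step that the worm does not move at all.
    heading_persistence:
        In [0, 1]; 1 keeps the previous heading exactly, 0 draws a fresh
        uniform heading each step.
    seed:
        Per-strain entropy mixed into the scene seed.
    """

    name: str
    speed_scale: float
    pause_prob: float = 0.05
    heading_persistence: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_scale < 0:
            raise InvalidParameterError("speed_scale must be >= 0")
        if not 0.0 <= self.pause_prob <= 1.0:
            raise InvalidParameterError("pause_prob must be in [0, 1]")
        if not 0.0 <= self.heading_persistence <= 1.0:
            raise InvalidParameterError("heading_persistence must be in [0, 1]")


# Strain presets: stand-ins for N2-like, mild-deficit and severely
# uncoordinated phenotypes.  Speeds sit in the usual C. elegans crawl range;
# the mild preset reduces speed by ~27% relative to wild-type-like.
WT_LIKE = StrainMotilityModel("wt-like", speed_scale=150.0, pause_prob=0.05,
                              heading_persistence=0.9, seed=1)
MILD_DEFICIT = StrainMotilityModel("mild-deficit", speed_scale=110.0,
                                   pause_prob=0.10, heading_persistence=0.9,
                                   seed=2)
SEVERE_UNCOORDINATED = StrainMotilityModel("severe-unc", speed_scale=25.0,
                                           pause_prob=0.50,
                                           heading_persistence=0.6, seed=3)
STRAIN_PRESETS = {
    m.name: m for m in (WT_LIKE, MILD_DEFICIT, SEVERE_UNCOORDINATED)
}


@dataclass
class WormTrajectory:
    """Ground-truth path of a single 1-mm worm on the plate plane."""

    worm_id: int
    positions: np.ndarray  # (n_instants, 2) world mm
    headings: np.ndarray  # (n_instants,) rad
    body_length: float = 1.0  # mm
    body_width: float = 80.0  # um
    strain: str = ""

    def position_at(self, t: float, dt: float) -> np.ndarray:
        """Linearly interpolated world position at time ``t``."""
        idx = t / dt
        lo = int(math.floor(idx))
        lo = min(max(lo, 0), len(self.positions) - 1)
        hi = min(lo + 1, len(self.positions) - 1)
        frac = idx - lo
        return (1 - frac) * self.positions[lo] + frac * self.positions[hi]


@dataclass
class PlateScene:
    """A simulated plate: geometry, time base, and worm trajectories."""

    worms: list[WormTrajectory]
    duration: float  # s
    dt: float  # s
    plate_radius: float = PLATE_RADIUS_MM  # mm

    @property
    def n_instants(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_instants) * self.dt

    def positions_at(self, t: float) -> np.ndarray:
        """(n_worms, 2) array of ground-truth world positions at time t."""
        return np.array([w.position_at(t, self.dt) for w in self.worms]).reshape(-1, 2)


@dataclass
class CameraModel:
    """Pinhole-free scaled orthographic camera, macro or micro.

    ``scale`` is um per pixel; ``centre_world`` is the world point imaged at
    the geometric image centre (for the micro camera this is the head
    position and is passed per frame).
    """

    scale: float  # um/pxl
    image_size: tuple[int, int]  # (rows, cols)
    centre_world: tuple[float, float] = (0.0, 0.0)  # mm
    focus_z: float = 0.0  # steps (micro only)
    defocus_gain: float = 0.0  # blur sigma (pxl) per step of |z - focus_z|

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidParameterError("camera scale must be > 0")

    @property
    def scale_mm(self) -> float:
        return self.scale * 1e-3

    def world_to_pixel(self, p, centre: Optional[tuple[float, float]] = None) -> np.ndarray:
        """Map world (x, y) mm -> pixel (x=col, y=row); row grows downward."""
        cx, cy = centre if centre is not None else self.centre_world
        p = np.asarray(p, dtype=float)
        rows, cols = self.image_size
        px = (p[..., 0] - cx) / self.scale_mm + (cols - 1) / 2.0
        py = (cy - p[..., 1]) / self.scale_mm + (rows - 1) / 2.0
        return np.stack([px, py], axis=-1)

    def pixel_to_world(self, q, centre: Optional[tuple[float, float]] = None) -> np.ndarray:
        cx, cy = centre if centre is not None else self.centre_world
        q = np.asarray(q, dtype=float)
        rows, cols = self.image_size
        x = (q[..., 0] - (cols - 1) / 2.0) * self.scale_mm + cx
        y = cy - (q[..., 1] - (rows - 1) / 2.0) * self.scale_mm
        return np.stack([x, y], axis=-1)


def macro_camera(image_size: tuple[int, int] = (1944, 2592),
                 scale: float = 27.31) -> CameraModel:
    """Whole-plate camera at the rig's macro resolution (27.31 um/pxl)."""
    return CameraModel(scale=scale, image_size=image_size)


def micro_camera(image_size: tuple[int, int] = (1944, 2592),
                 scale: float = 1.09, focus_z: float = 0.0,
                 defocus_gain: float = 0.05) -> CameraModel:
    """Head-mounted high-resolution camera (1.09 um/pxl)."""
    return CameraModel(scale=scale, image_size=image_size,
                       focus_z=focus_z, defocus_gain=defocus_gain)


@dataclass
class Frame:
    """One grey-level image with its acquisition metadata."""

    pixels: np.ndarray  # float grey levels in [0, 255]
    t: float
    camera: CameraModel
    kind: str  # "macro" | "micro"

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def simulate_trajectories(models: Sequence[StrainMotilityModel],
                          n_worms_per_model: int,
                          duration: float,
                          dt: float,
                          seed: int,
                          plate_radius: float = PLATE_RADIUS_MM,
                          edge_margin: float = 1.0,
                          spawn_radius_frac: float = 0.8,
                          body_width_um: float = 80.0) -> PlateScene:
    """Simulate persistent-random-walk trajectories for every strain model.

    Each worm updates its heading as a persistence-weighted turn (turn angle
    = ``(1 - heading_persistence) * Uniform(-pi, pi)``) and advances by an
    exponentially distributed speed sample times ``dt``, zeroed with
    probability ``pause_prob``.  Worms reflect off a wall at
    ``plate_radius - edge_margin`` so the population on the plate is
    constant, as in a walled dish.

    Identical ``seed`` (and parameters) gives a bit-identical scene.
    """
    if dt <= 0 or duration <= 0:
        raise InvalidParameterError("duration and dt must be > 0")
    if n_worms_per_model < 0:
        raise InvalidParameterError("n_worms_per_model must be >= 0")

    n_steps = int(round(duration / dt))
    r_wall = plate_radius - edge_margin
    worms: list[WormTrajectory] = []
    wid = 0
    for model in models:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, model.seed, n_worms_per_model]))
        for _ in range(n_worms_per_model):
            pos = np.empty((n_steps + 1, 2))
            head = np.empty(n_steps + 1)
            r0 = r_wall * spawn_radius_frac * math.sqrt(rng.uniform())
            th0 = rng.uniform(0, 2 * math.pi)
            pos[0] = (r0 * math.cos(th0), r0 * math.sin(th0))
            head[0] = rng.uniform(-math.pi, math.pi)
            speed_mm = model.speed_scale * 1e-3  # um/s -> mm/s
            for k in range(n_steps):
                turn = (1.0 - model.heading_persistence) * rng.uniform(-math.pi, math.pi)
                theta = head[k] + turn
                if rng.uniform() < model.pause_prob:
                    step = 0.0
                else:
                    step = speed_mm * rng.exponential() * dt
                p = pos[k] + step * np.array([math.cos(theta), math.sin(theta)])
                r = float(np.hypot(p[0], p[1]))
                if r > r_wall:
                    # reflect radially back inside the wall
                    p *= (2.0 * r_wall - r) / r
                    theta = math.atan2(p[1] - pos[k][1], p[0] - pos[k][0])
                pos[k + 1] = p
                head[k + 1] = theta
            worms.append(WormTrajectory(worm_id=wid, positions=pos,
                                        headings=head,
                                        body_width=body_width_um,
                                        strain=model.name))
            wid += 1
    return PlateScene(worms=worms, duration=duration, dt=dt,
                      plate_radius=plate_radius)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _draw_capsule(img: np.ndarray, centre_px: np.ndarray, heading: float,
                  length_px: float, width_px: float, value: float) -> None:
    """Paint an oriented capsule (rectangle + end caps) into ``img``."""
    # pixel frame: heading angle is measured in world (y up), flip for rows
    ux, uy = math.cos(heading), -math.sin(heading)
    nx, ny = -uy, ux
    hl, hw = length_px / 2.0, max(width_px / 2.0, 0.5)
    cx, cy = centre_px
    corners_c = [cx + sx * hl * ux + sy * hw * nx
                 for sx, sy in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
    corners_r = [cy + sx * hl * uy + sy * hw * ny
                 for sx, sy in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
    rr, cc = draw_polygon(corners_r, corners_c, shape=img.shape)
    img[rr, cc] = value
    for end in (1, -1):
        rr, cc = draw_disk((cy + end * hl * uy, cx + end * hl * ux), hw,
                           shape=img.shape)
        img[rr, cc] = value


def render_macro_frame(scene: PlateScene, t: float,
                       backlight=DEFAULT_BACKLIGHT,
                       laser_spot: Optional[tuple[float, float]] = None,
                       camera: Optional[CameraModel] = None,
                       contrast: float = DEFAULT_WORM_CONTRAST,
                       laser_radius_px: float = 2.0,
                       double_spot: bool = False) -> Frame:
    """Render the whole-plate view at time ``t``.

    ``backlight`` is either a uniform grey level or a full-size field (the
    output of the active-vision loop mapped into pixel space).  Worms render
    as dark capsules ``contrast`` grey levels below the local backlight.
    ``laser_spot`` (pixel x, y) renders as a small saturated disc; with
    ``double_spot`` a second, larger and dimmer disc is added at the same
    position, mimicking the beamsplitter reflection that makes the
    macrocamera capture the laser twice.
    """
    if camera is None:
        camera = macro_camera()
    if not 0.0 <= t <= scene.duration + 1e-9:
        raise InvalidParameterError(f"t={t} outside scene duration {scene.duration}")

    img = np.empty(camera.image_size, dtype=float)
    img[:] = backlight
    for worm in scene.worms:
        centre = camera.world_to_pixel(worm.position_at(t, scene.dt))
        heading = worm.headings[min(int(round(t / scene.dt)),
                                    len(worm.headings) - 1)]
        length_px = worm.body_length * 1e3 / camera.scale
        width_px = worm.body_width / camera.scale
        if np.isscalar(backlight):
            local = backlight
        else:
            bl = np.asarray(backlight)
            r = int(np.clip(round(centre[1]), 0, camera.image_size[0] - 1))
            c = int(np.clip(round(centre[0]), 0, camera.image_size[1] - 1))
            local = float(bl[r, c])
        _draw_capsule(img, centre, heading, length_px, width_px,
                      max(float(local) - contrast, 0.0))
    if laser_spot is not None:
        if double_spot:
            rr, cc = draw_disk((laser_spot[1], laser_spot[0]),
                               2.0 * laser_radius_px, shape=img.shape)
            img[rr, cc] = np.minimum(img[rr, cc] + 40.0, 255.0)
        rr, cc = draw_disk((laser_spot[1], laser_spot[0]), laser_radius_px,
                           shape=img.shape)
        img[rr, cc] = 255.0
    np.clip(img, 0, 255, out=img)
    return Frame(pixels=img, t=t, camera=camera, kind="macro")


def render_micro_frame(scene: PlateScene, t: float,
                       head_world: tuple[float, float], z: float,
                       camera: Optional[CameraModel] = None,
                       backlight: float = DEFAULT_BACKLIGHT,
                       contrast: float = DEFAULT_WORM_CONTRAST) -> Frame:
    """Render the high-resolution crop centred on the robot head.

    Defocus is modelled as a Gaussian blur of sigma
    ``defocus_gain * |z - focus_z|`` pixels; the frame is sharpest exactly
    at the camera's ``focus_z``.  Regions outside the plate render as
    background.
    """
    if camera is None:
        camera = micro_camera()
    img = np.empty(camera.image_size, dtype=float)
    img[:] = backlight
    half_diag_mm = 0.5 * math.hypot(*camera.image_size) * camera.scale_mm
    for worm in scene.worms:
        pos = worm.position_at(t, scene.dt)
        if np.hypot(*(pos - np.asarray(head_world))) > half_diag_mm + worm.body_length:
            continue
        centre = camera.world_to_pixel(pos, centre=head_world)
        heading = worm.headings[min(int(round(t / scene.dt)),
                                    len(worm.headings) - 1)]
        _draw_capsule(img, centre, heading,
                      worm.body_length * 1e3 / camera.scale,
                      worm.body_width / camera.scale,
                      max(backlight - contrast, 0.0))
    sigma = camera.defocus_gain * abs(z - camera.focus_z)
    if sigma > 0:
        img = gaussian(img, sigma=sigma, preserve_range=True)
    np.clip(img, 0, 255, out=img)
    return Frame(pixels=img, t=t, camera=camera, kind="micro")
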