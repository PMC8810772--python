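"""Active illumination: backlight feedback control and the sigmoid circle.

The backlight display and the macro camera form a closed loop: the display
is calibrated against the camera (a projective texel-to-pixel map fitted on
dot patterns), then a proportional controller brightens the texels whose
associated image pixels read darker than a reference grey level and dims
those that read brighter, until the whole macro image sits at the
reference.  During micro capture a high-intensity circle centred on the
worm-goal position is drawn on top; its edge follows a logistic profile in
the distance to the centre so illumination gradients stay small enough for
adaptive-threshold segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import center_of_mass, label
from skimage.transform import ProjectiveTransform, estimate_transform

from .errors import CalibrationError, InvalidParameterError
from .scene_sim import Frame

__all__ = [
    "DISPLAY_SHAPE",
    "LightingState",
    "TexelPixelMap",
    "SigmoidCircleSpec",
    "calibrate_texel_map",
    "make_dot_pattern",
    "update_backlight",
    "sigmoid_circle_pattern",
]

#: The rig's 7-inch display resolution, (rows, cols) of texels.
DISPLAY_SHAPE = (480, 800)


@dataclass
class LightingState:
    """Grey-level intensity of every display texel, clipped to [0, 255]."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.clip(np.asarray(self.intensities, dtype=float),
                                   0, 255)

    @classmethod
    def uniform(cls, level: float, shape: tuple[int, int] = DISPLAY_SHAPE
                ) -> "LightingState":
        return cls(np.full(shape, float(level)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class TexelPixelMap:
    """Projective map from display texel (x, y) to macro pixel (x, y)."""

    transform: ProjectiveTransform
    residual: float = 0.0  # RMS pixel residual of the calibration fit

    def texel_to_pixel(self, pts: np.ndarray) -> np.ndarray:
        return self.transform(np.asarray(pts, dtype=float).reshape(-1, 2))

    def pixel_to_texel(self, pts: np.ndarray) -> np.ndarray:
        return self.transform.inverse(np.asarray(pts, dtype=float).reshape(-1, 2))

    @property
    def matrix(self) -> np.ndarray:
        return self.transform.params


@dataclass(frozen=True)
class SigmoidCircleSpec:
    """High-intensity illumination circle with a logistic edge profile."""

    centre: tuple[float, float]  # pixel (x, y)
    radius: float  # pxl
    low: float  # grey level far from the circle
    high: float  # grey level inside the circle
    slope: float = 10.0  # transition width, pxl

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise InvalidParameterError("low must be <= high")
        if self.radius <= 0 or self.slope <= 0:
            raise InvalidParameterError("radius and slope must be > 0")


def make_dot_pattern(texel_xy: tuple[float, float], dot_half: int = 1,
                     level: float = 255.0,
                     shape: tuple[int, int] = DISPLAY_SHAPE) -> LightingState:
    """Lighting state with a single bright square dot at a texel position."""
    img = np.zeros(shape)
    x, y = int(round(texel_xy[0])), int(round(texel_xy[1]))
    img[max(y - dot_half, 0):y + dot_half + 1,
        max(x - dot_half, 0):x + dot_half + 1] = level
    return LightingState(img)


def _blob_centroid(img: np.ndarray, threshold: float) -> np.ndarray | None:
    """Intensity-weighted centroid (x, y) of the brightest blob above threshold."""
    mask = img > threshold
    if not mask.any():
        return None
    labels, n = label(mask)
    if n > 1:
        sums = np.bincount(labels.ravel(), weights=img.ravel())[1:]
        keep = int(np.argmax(sums)) + 1
        mask = labels == keep
    weights = np.where(mask, img, 0.0)
    cy, cx = center_of_mass(weights)
    return np.array([cx, cy])


def calibrate_texel_map(pattern_frames: list[tuple[LightingState, Frame]],
                        detect_threshold: float | None = None
                        ) -> TexelPixelMap:
    """Fit the projective texel-to-pixel transform from dot patterns.

    Each calibration shot lights one (or one dominant) dot on the display;
    the dot's texel centroid and its detected image centroid form one
    correspondence.  At least 4 non-collinear correspondences are required
    for the projective least-squares fit.
    """
    src, dst = [], []
    for state, frame in pattern_frames:
        tex = _blob_centroid(state.intensities, 0.0)
        thr = (detect_threshold if detect_threshold is not None
               else float(np.median(frame.pixels)) + 10.0)
        pix = _blob_centroid(frame.pixels, thr)
        if tex is None or pix is None:
            continue
        src.append(tex)
        dst.append(pix)
    src, dst = np.array(src), np.array(dst)
    if len(src) < 4:
        raise CalibrationError(
            f"only {len(src)} dot correspondences detected; need >= 4")
    # collinearity check: all points on one line make the fit degenerate
    centred = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-6) < 2:
        raise CalibrationError("calibration dots are collinear")
    tf = estimate_transform("projective", src, dst)
    if not np.all(np.isfinite(tf.params)):
        raise CalibrationError("projective fit did not converge")
    residual = float(np.sqrt(np.mean(np.sum((tf(src) - dst) ** 2, axis=1))))
    return TexelPixelMap(transform=tf, residual=residual)


def texel_ownership(map_: TexelPixelMap, image_shape: tuple[int, int],
                    display_shape: tuple[int, int] = DISPLAY_SHAPE
                    ) -> np.ndarray:
    """Flat texel index owning each image pixel (nearest mapped texel).

    Computed by inverse-mapping every pixel centre to texel coordinates and
    rounding; pixels falling outside the display get index -1.
    """
    rows, cols = image_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    tex = map_.pixel_to_texel(pix)
    tx = np.rint(tex[:, 0]).astype(int)
    ty = np.rint(tex[:, 1]).astype(int)
    ok = (tx >= 0) & (tx < display_shape[1]) & (ty >= 0) & (ty < display_shape[0])
    idx = np.where(ok, ty * display_shape[1] + tx, -1)
    return idx.reshape(image_shape)


def update_backlight(frame: Frame, reference: float, map_: TexelPixelMap,
                     state: LightingState, gain: float = 0.5,
                     ownership: np.ndarray | None = None) -> LightingState:
    """One proportional step of the luminance control loop.

    Each texel owns the image pixels nearest its mapped centre; its level
    changes by ``gain * (reference - mean grey of owned pixels)``, so texels
    behind darker-than-reference pixels get brighter and vice versa.
    Texels owning no pixels are left unchanged.  Output is clipped to
    [0, 255].
    """
    if gain <= 0:
        raise InvalidParameterError("gain must be > 0")
    if ownership is None:
        ownership = texel_ownership(map_, frame.pixels.shape, state.shape)
    n_tex = state.intensities.size
    idx = ownership.ravel()
    valid = idx >= 0
    counts = np.bincount(idx[valid], minlength=n_tex).astype(float)
    sums = np.bincount(idx[valid], weights=frame.pixels.ravel()[valid],
                       minlength=n_tex)
    mean = np.divide(sums, counts, out=np.full(n_tex, float(reference)),
                     where=counts > 0)
    delta = gain * (reference - mean)
    new = state.intensities.ravel() + delta
    return LightingState(new.reshape(state.shape))


def sigmoid_circle_pattern(spec: SigmoidCircleSpec,
                           grid_shape: tuple[int, int]) -> np.ndarray:
    """Radially symmetric intensity field with a logistic circle edge.

    I(d) = low + (high - low) * logistic((radius - d) / slope), with d the
    Euclidean distance to the centre: ``high`` at the centre, ``low`` far
    outside, exactly the midpoint on the circle itself.  The maximum radial
    gradient is (high - low) / (4 * slope) per pixel, which is what keeps
    the illumination gradients small.
    """
    rows, cols = grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    d = np.hypot(xx - spec.centre[0], yy - spec.centre[1])
    z = (spec.radius - d) / spec.slope
    logistic = 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable expit
    return spec.low + (spec.high - spec.low) * logistic
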