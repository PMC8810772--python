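"""Whole-plate software tracking: segment, size-filter, associate identities.

Macro image processing runs in three steps on every whole-plate frame:

1. adaptive-threshold segmentation — a pixel is foreground when it is
   darker than its local mean by more than a configured offset, which keeps
   worm silhouettes separable even under the illumination gradients the
   micro lighting circle introduces;
2. size classification — connected components (8-connectivity) are kept
   only when their area falls in a worm-sized gate;
3. identity tracking — detections are matched to the previous frame's worm
   positions by minimum total Euclidean distance (optimal bipartite
   assignment).  Matches longer than a gating distance are broken, merged
   worms lose their identity, and such events are recorded as censoring —
   worms are never re-identified after contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.optimize import linear_sum_assignment
from skimage.measure import label, regionprops

from .errors import InvalidParameterError
from .scene_sim import Frame

__all__ = [
    "Detection",
    "SegmentationParams",
    "TrackTable",
    "segment_adaptive",
    "classify_by_size",
    "associate_identities",
]


@dataclass(frozen=True)
class Detection:
    """One segmented blob in a macro frame."""

    centroid: tuple[float, float]  # (x, y) pxl
    area: int  # pxl^2
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    frame_t: float = 0.0


@dataclass(frozen=True)
class SegmentationParams:
    """Adaptive threshold and tracking gates.

    window:   side of the square local-mean neighbourhood, odd, >= 3
    offset:   grey levels below the local mean needed to be foreground
    min_area, max_area:  connected-component size gate, pxl^2
    max_jump: association gate, pxl; identity breaks past this distance
    """

    window: int = 25
    offset: float = 15.0
    min_area: int = 20
    max_area: int = 600
    max_jump: float = 60.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise InvalidParameterError("window must be odd and >= 3")
        if self.min_area >= self.max_area:
            raise InvalidParameterError("min_area must be < max_area")
        if self.max_jump <= 0:
            raise InvalidParameterError("max_jump must be > 0")


def segment_adaptive(frame: Frame, params: SegmentationParams) -> np.ndarray:
    """Boolean foreground mask: pixel < local mean over window − offset."""
    img = np.asarray(frame.pixels, dtype=float)
    if img.size == 0:
        raise InvalidParameterError("empty frame")
    if params.window > min(img.shape):
        raise InvalidParameterError(
            f"window {params.window} larger than image {img.shape}")
    local_mean = uniform_filter(img, size=params.window, mode="reflect")
    return img < local_mean - params.offset


def classify_by_size(mask: np.ndarray, params: SegmentationParams,
                     frame_t: float = 0.0) -> list[Detection]:
    """Label the mask (8-connectivity) and keep worm-sized components."""
    if mask.dtype == bool:
        labelled = label(mask, connectivity=2)
    else:
        labelled = mask
    out: list[Detection] = []
    for region in regionprops(labelled):
        if params.min_area <= region.area <= params.max_area:
            cy, cx = region.centroid
            out.append(Detection(centroid=(float(cx), float(cy)),
                                 area=int(region.area),
                                 bbox=tuple(region.bbox),
                                 frame_t=frame_t))
    return out


def associate_identities(prev: list[tuple[int, tuple[float, float]]],
                         current: list[Detection],
                         max_jump: float
                         ) -> tuple[dict[int, Detection], list[int], list[Detection]]:
    """Match previous worm positions to current detections by minimum distance.

    Returns ``(assignment, censored_ids, unmatched_detections)``:
    the optimal (minimum total Euclidean distance) bipartite assignment,
    with any pair further apart than ``max_jump`` broken — the old identity
    is censored and the detection is treated as new.  Identities lost to
    merges (fewer detections than worms) are censored likewise.
    """
    if not prev:
        return {}, [], list(current)
    if not current:
        return {}, [wid for wid, _ in prev], []
    prev = sorted(prev, key=lambda item: item[0])  # stable: lowest id first
    p = np.array([pos for _, pos in prev], dtype=float)
    c = np.array([d.centroid for d in current], dtype=float)
    cost = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    assignment: dict[int, Detection] = {}
    censored: list[int] = []
    matched_det = set()
    for r, col in zip(rows, cols):
        wid = prev[r][0]
        if cost[r, col] <= max_jump:
            assignment[wid] = current[col]
            matched_det.add(col)
        else:
            censored.append(wid)
    matched_ids = set(assignment) | set(censored)
    censored.extend(wid for wid, _ in prev if wid not in matched_ids)
    unmatched = [d for i, d in enumerate(current) if i not in matched_det]
    return assignment, sorted(censored), unmatched


@dataclass
class TrackTable:
    """Per-worm detection history with persistent, never-reused identities."""

    tracks: dict[int, list[Detection]] = field(default_factory=dict)
    censored: dict[int, float] = field(default_factory=dict)  # id -> t of event
    tested_set: set[int] = field(default_factory=set)
    misses: dict[int, int] = field(default_factory=dict)
    _next_id: int = 0

    def update(self, detections: list[Detection], t: float,
               max_jump: float, max_misses: int = 0) -> None:
        """Ingest one frame's detections, tracking identities.

        ``max_misses`` frames of missing detection are tolerated (the track
        coasts at its last position) before the identity is censored; 0
        censors on the first loss.
        """
        prev = [(wid, trk[-1].centroid) for wid, trk in self.tracks.items()
                if wid not in self.censored]
        assignment, lost, unmatched = associate_identities(
            prev, detections, max_jump)
        for wid, det in assignment.items():
            self.tracks[wid].append(det)
            self.misses[wid] = 0
        for wid in lost:
            self.misses[wid] = self.misses.get(wid, 0) + 1
            if self.misses[wid] > max_misses:
                self.censored[wid] = t
        for det in unmatched:
            self.tracks[self._next_id] = [det]
            self._next_id += 1

    @property
    def active_ids(self) -> list[int]:
        return sorted(wid for wid in self.tracks if wid not in self.censored)

    def last_position(self, wid: int) -> tuple[float, float]:
        return self.tracks[wid][-1].centroid

    def mark_tested(self, wid: int) -> None:
        self.tested_set.add(wid)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for wid, dets in sorted(self.tracks.items()):
            for det in dets:
                rows.append({"worm_id": wid, "t": det.frame_t,
                             "cx_pxl": det.centroid[0],
                             "cy_pxl": det.centroid[1],
                             "area": det.area,
                             "censored": wid in self.censored
                             and det.frame_t >= self.censored[wid]})
        return pd.DataFrame(rows, columns=["worm_id", "t", "cx_pxl",
                                           "cy_pxl", "area", "censored"])
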