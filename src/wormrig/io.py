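"""Readers and writers for the package's plain-text interchange formats.

Every writer has a matching reader whose output round-trips: trajectory
tables and session logs as CSV, comparison reports as JSON, frames as
8-bit PNG, configs as YAML/JSON (see `wormrig.config`).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .macrotracking import TrackTable, Detection
from .motility_metrics import ComparisonReport, HistogramSpec
from .scene_sim import Frame, PlateScene, WormTrajectory
from .tracking_controller import MachineState, SessionLog

__all__ = [
    "write_trajectories", "read_trajectories",
    "write_tracktable", "read_tracktable",
    "write_sessionlog", "read_sessionlog",
    "write_report", "read_report",
    "write_frame",
]

_TRAJ_COLS = ["worm_id", "t", "x_mm", "y_mm", "heading_rad", "strain"]


def write_trajectories(scene: PlateScene, path: str | Path) -> None:
    rows = []
    times = scene.times
    for worm in scene.worms:
        for t, (x, y), h in zip(times, worm.positions, worm.headings):
            rows.append((worm.worm_id, t, x, y, h, worm.strain))
    pd.DataFrame(rows, columns=_TRAJ_COLS).to_csv(path, index=False)


def read_trajectories(path: str | Path, plate_radius: float = 27.5
                      ) -> PlateScene:
    df = pd.read_csv(path)
    worms = []
    times = np.sort(df["t"].unique())
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    for wid, grp in df.groupby("worm_id"):
        grp = grp.sort_values("t")
        worms.append(WormTrajectory(
            worm_id=int(wid),
            positions=grp[["x_mm", "y_mm"]].to_numpy(),
            headings=grp["heading_rad"].to_numpy(),
            strain=str(grp["strain"].iloc[0]) if "strain" in grp else ""))
    duration = float(times[-1] - times[0]) if len(times) > 1 else 0.0
    return PlateScene(worms=worms, duration=duration, dt=dt,
                      plate_radius=plate_radius)


def write_tracktable(table: TrackTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_tracktable(path: str | Path) -> TrackTable:
    df = pd.read_csv(path)
    table = TrackTable()
    for wid, grp in df.groupby("worm_id"):
        dets = [Detection(centroid=(r.cx_pxl, r.cy_pxl), area=int(r.area),
                          bbox=(0, 0, 0, 0), frame_t=float(r.t))
                for r in grp.sort_values("t").itertuples()]
        table.tracks[int(wid)] = dets
        flagged = grp[grp["censored"]]
        if len(flagged):
            table.censored[int(wid)] = float(flagged["t"].min())
    table._next_id = max(table.tracks, default=-1) + 1
    return table


def write_sessionlog(log: SessionLog, path: str | Path) -> None:
    log.to_dataframe().to_csv(path, index=False)


def read_sessionlog(path: str | Path) -> SessionLog:
    df = pd.read_csv(path)
    log = SessionLog()
    for r in df.itertuples():
        log.log_action(int(r.worm_id), int(r.k), float(r.t),
                       int(r.dx_steps), int(r.dy_steps),
                       MachineState(r.state))
    return log


def write_report(report: ComparisonReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def read_report(path: str | Path) -> ComparisonReport:
    data = json.loads(Path(path).read_text())
    return ComparisonReport(
        strains=data["strains"],
        per_worm_sums={s: {int(k): v for k, v in d.items()}
                       for s, d in data["per_worm_sums"].items()},
        per_worm_percent={s: {int(k): v for k, v in d.items()}
                          for s, d in data["per_worm_percent"].items()},
        p_values={tuple(key.split("|")): p
                  for key, p in data["p_values"].items()},
        histograms={s: np.asarray(h) for s, h in data["histograms"].items()},
        histogram_spec=HistogramSpec(),
    )


def write_frame(frame: Frame, path: str | Path) -> None:
    iio.imwrite(Path(path), frame.to_uint8())
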