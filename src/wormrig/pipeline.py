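"""End-to-end pipeline: simulate plates, track, measure, compare strains.

The full experiment mirrors the rig's protocol: several replicate plates
per strain (~30 worms each), displacement modules per worm at the 2 fps
capture rate, then the pairwise rank-sum comparison.  Metrics can be
computed image-free from the ground-truth trajectories (fast, default) or
from closed-loop session logs (control actions of the simulated robot).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io as rio
from . import motility_metrics as mm
from . import robot_model as rm
from . import scene_sim as sim
from . import tracking_controller as tc
from .config import RunConfig
from .macrotracking import SegmentationParams

logger = logging.getLogger("wormrig")

__all__ = ["run_pipeline", "simulate_replicates", "modules_from_scene",
           "modules_from_sessionlog", "compare_from_config"]


def simulate_replicates(config: RunConfig) -> dict[str, list[sim.PlateScene]]:
    """One scene per (strain, replicate): separate plates, as on the rig."""
    scenes: dict[str, list[sim.PlateScene]] = {}
    for strain_cfg in config.scene.strains:
        model = strain_cfg.to_model()
        scenes[model.name] = []
        for rep in range(config.scene.n_replicates):
            scene = sim.simulate_trajectories(
                [model], config.scene.n_worms_per_plate,
                duration=config.scene.duration, dt=config.scene.dt,
                seed=(config.seed * 1000 + rep) % (2 ** 31),
                plate_radius=config.scene.plate_radius)
            scenes[model.name].append(scene)
    return scenes


def modules_from_scene(scene: sim.PlateScene, sample_dt: float,
                       step_size_mm: float = rm.STEP_SIZE_MM,
                       id_offset: int = 0) -> list[mm.ModuleSeries]:
    """Ground-truth displacement modules sampled at the capture rate.

    Positions are sampled every ``sample_dt`` seconds and converted to
    motor steps, matching what the microtracking control actions measure.
    """
    times = np.arange(0.0, scene.duration + 1e-9, sample_dt)
    out = []
    for worm in scene.worms:
        pos_mm = np.array([worm.position_at(t, scene.dt) for t in times])
        pos_steps = pos_mm / step_size_mm
        out.append(mm.displacement_modules(pos_steps,
                                           worm_id=worm.worm_id + id_offset,
                                           strain=worm.strain))
    return out


def modules_from_sessionlog(log: tc.SessionLog, strain: str = "",
                            id_offset: int = 0) -> list[mm.ModuleSeries]:
    """Displacement modules from the logged control actions (steps)."""
    out = []
    for wid in sorted({a["worm_id"] for a in log.actions}):
        deltas = log.actions_for(wid)
        if len(deltas) == 0:
            continue
        out.append(mm.displacement_modules(deltas, worm_id=wid + id_offset,
                                           strain=strain, kind="deltas"))
    return out


def compare_from_config(config: RunConfig) -> mm.ComparisonReport:
    """Simulate all plates and run the strain comparison, image-free."""
    scenes = simulate_replicates(config)
    sample_dt = 1.0 / config.controller.micro_rate
    groups: dict[str, list[mm.ModuleSeries]] = {}
    for strain, replicates in scenes.items():
        series: list[mm.ModuleSeries] = []
        for scene in replicates:
            series.extend(modules_from_scene(
                scene, sample_dt, step_size_mm=config.rig.step_size_mm,
                id_offset=len(series)))
        groups[strain] = series
    spec = mm.HistogramSpec(tuple(config.metrics.bin_edges))
    return mm.compare_strains(groups, spec=spec,
                              normalization=config.metrics.normalization)


def _controller_config(config: RunConfig) -> tc.ControllerConfig:
    ctl = config.controller
    return tc.ControllerConfig(
        macro_camera=config.rig.macro_camera.to_model(),
        micro_camera=config.rig.micro_camera.to_model(),
        step_model=config.rig.step_model(),
        schedule=tc.CaptureSchedule(macro_rate=ctl.macro_rate,
                                    micro_rate=ctl.micro_rate,
                                    micro_duration=ctl.micro_duration),
        seg_params=SegmentationParams(window=ctl.seg_window,
                                      offset=ctl.seg_offset,
                                      min_area=ctl.min_area,
                                      max_area=ctl.max_area,
                                      max_jump=ctl.max_jump),
        acquisition_error_px=ctl.acquisition_error_px,
        acquisition_retries=ctl.acquisition_retries,
        store_frames=ctl.store_frames)


def run_pipeline(config: RunConfig, outdir: str | Path,
                 track: bool = False, write_frames: bool = False) -> Path:
    """Run the full experiment and write all artifacts to ``outdir``.

    With ``track=True`` the closed-loop controller is run on the first
    replicate of every strain and its session log and track table are
    written alongside the image-free metrics (which cover all replicates).
    Rerunning with the same config and seed reproduces the trajectory and
    metric files bit for bit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.model_dump_json(indent=2))
    logger.info("simulating %d strains x %d replicates",
                len(config.scene.strains), config.scene.n_replicates)
    scenes = simulate_replicates(config)
    for strain, replicates in scenes.items():
        for rep, scene in enumerate(replicates):
            rio.write_trajectories(
                scene, outdir / f"trajectories_{strain}_rep{rep}.csv")

    if track:
        ctl_cfg = _controller_config(config)
        for strain, replicates in scenes.items():
            log, table, frames = tc.run_session(replicates[0], ctl_cfg)
            rio.write_sessionlog(log, outdir / f"session_{strain}.csv")
            rio.write_tracktable(table, outdir / f"tracks_{strain}.csv")
            if write_frames:
                fdir = outdir / "frames" / strain
                fdir.mkdir(parents=True, exist_ok=True)
                for wid, flist in frames.items():
                    for i, frame in enumerate(flist):
                        rio.write_frame(frame, fdir / f"worm{wid}_{i:03d}.png")

    report = compare_from_config(config)
    rio.write_report(report, outdir / "comparison.json")
    metrics_rows = []
    for strain, sums in report.per_worm_sums.items():
        for wid, total in sums.items():
            metrics_rows.append({
                "strain": strain, "worm_id": wid, "module_sum_steps": total,
                "percent": report.per_worm_percent[strain][wid]})
    import pandas as pd
    pd.DataFrame(metrics_rows).to_csv(outdir / "per_worm_metrics.csv",
                                      index=False)
    hist = {s: list(map(float, h)) for s, h in report.histograms.items()}
    (outdir / "histograms.json").write_text(json.dumps(
        {"labels": report.histogram_spec.labels, "frequencies": hist},
        indent=2))
    logger.info("pipeline complete: %s", outdir)
    return outdir
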