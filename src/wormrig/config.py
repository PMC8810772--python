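"""Run configuration: one schema-validated document drives the pipeline.

Defaults mirror the physical rig (camera scales, sensor size, motion
limits, capture schedule) or the package's documented design choices
(strain presets, segmentation gates, histogram bins).  Schema violations
are reported with their field paths via pydantic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError

from . import robot_model as rm
from . import scene_sim as sim
from .errors import InvalidParameterError

__all__ = ["RunConfig", "load_config", "default_config"]


class StrainConfig(BaseModel):
    name: str
    speed_scale: float = Field(ge=0, description="mean crawl speed, um/s")
    pause_prob: float = Field(default=0.05, ge=0, le=1)
    heading_persistence: float = Field(default=0.9, ge=0, le=1)
    seed: int = 0

    def to_model(self) -> sim.StrainMotilityModel:
        return sim.StrainMotilityModel(**self.model_dump())


class SceneConfig(BaseModel):
    plate_radius: float = Field(default=sim.PLATE_RADIUS_MM, gt=0)
    n_worms_per_plate: int = Field(default=30, ge=0)
    n_replicates: int = Field(default=4, ge=1)
    duration: float = Field(default=30.0, gt=0, description="s")
    dt: float = Field(default=0.5, gt=0, description="s")
    strains: list[StrainConfig] = Field(
        default_factory=lambda: [
            StrainConfig(name=m.name, speed_scale=m.speed_scale,
                         pause_prob=m.pause_prob,
                         heading_persistence=m.heading_persistence,
                         seed=m.seed)
            for m in (sim.WT_LIKE, sim.MILD_DEFICIT,
                      sim.SEVERE_UNCOORDINATED)])


class CameraConfig(BaseModel):
    scale: float = Field(gt=0, description="um/pxl")
    image_rows: int = Field(gt=0)
    image_cols: int = Field(gt=0)
    focus_z: int = 0
    defocus_gain: float = Field(default=0.0, ge=0)

    def to_model(self) -> sim.CameraModel:
        return sim.CameraModel(scale=self.scale,
                               image_size=(self.image_rows, self.image_cols),
                               focus_z=self.focus_z,
                               defocus_gain=self.defocus_gain)


class RigConfig(BaseModel):
    macro_camera: CameraConfig = Field(
        default_factory=lambda: CameraConfig(scale=27.31, image_rows=1944,
                                             image_cols=2592))
    micro_camera: CameraConfig = Field(
        default_factory=lambda: CameraConfig(scale=1.09, image_rows=256,
                                             image_cols=256, focus_z=0,
                                             defocus_gain=0.05))
    step_size_mm: float = Field(default=rm.STEP_SIZE_MM, gt=0)
    step_scale_error: float = Field(
        default=1.0, gt=0,
        description="multiplier emulating pixel/step miscalibration")
    v_max: float = Field(default=8000.0, gt=0, description="stp/s")
    a_max: float = Field(default=25000.0, gt=0, description="stp/s^2")
    alpha_deg: float = Field(default=41.41 / 2, gt=0, lt=90,
                             description="half field of view")

    def step_model(self) -> rm.StepModel:
        return rm.step_model_from_cameras(
            self.macro_camera.to_model(), self.micro_camera.to_model(),
            step_size_mm=self.step_size_mm,
            scale_error=self.step_scale_error,
            v_max=self.v_max, a_max=self.a_max)


class ControllerParams(BaseModel):
    macro_rate: float = Field(default=1.0, gt=0, description="fps")
    micro_rate: float = Field(default=2.0, gt=0, description="fps")
    micro_duration: float = Field(default=30.0, gt=0, description="s")
    acquisition_error_px: float = Field(default=15.0, gt=0)
    acquisition_retries: int = Field(default=5, ge=1)
    seg_window: int = Field(default=25, ge=3)
    seg_offset: float = Field(default=15.0, ge=0)
    min_area: int = Field(default=20, ge=1)
    max_area: int = Field(default=600, ge=2)
    max_jump: float = Field(default=60.0, gt=0)
    store_frames: bool = False


class MetricsParams(BaseModel):
    bin_edges: list[float] = Field(default_factory=lambda: list(range(0, 11)))
    normalization: Literal["max", "group_total"] = "max"
    source: Literal["ground_truth", "session_log"] = "ground_truth"


class RunConfig(BaseModel):
    """Top-level configuration for the simulate->track->measure pipeline."""

    scene: SceneConfig = Field(default_factory=SceneConfig)
    rig: RigConfig = Field(default_factory=RigConfig)
    controller: ControllerParams = Field(default_factory=ControllerParams)
    metrics: MetricsParams = Field(default_factory=MetricsParams)
    seed: int = 1


def default_config(**overrides) -> RunConfig:
    return RunConfig(**overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config; errors carry field paths."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return RunConfig.model_validate(data or {})
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors())
        raise InvalidParameterError(f"invalid config {path}: {paths}") from exc
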