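"""Validated run configuration for end-to-end virtual sorting experiments."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .flowsim import AcquisitionConfig
from .pipeline import Gate, SegmentationParams
from .sorter import SortTimingConfig


class AcquisitionModel(BaseModel):
    line_rate: float = Field(48_000.0, gt=0)
    n_lateral_pixels: int = Field(24, gt=0)
    n_colors: int = Field(4, gt=0)
    lateral_fov: float = Field(24.0, gt=0)
    flow_fov: float = Field(33.0, gt=0)
    frame_lines: int = Field(122, gt=0)
    flow_speed: float = Field(0.04, gt=0)
    noise_sigma: float = Field(1.0 / 30.0, ge=0)
    fsc_pulse_width: float = Field(0.0, ge=0)

    def build(self, seed: int) -> AcquisitionConfig:
        return AcquisitionConfig(seed=seed, **self.model_dump())


class TimingModel(BaseModel):
    sort_window: float = Field(3e-3, gt=0)
    sort_latency: float = Field(0.0, ge=0)
    rate: float = Field(50.0, ge=0)
    r: float = Field(0.6, ge=0, le=1)
    flow_speed: float = Field(0.04, gt=0)

    def build(self) -> SortTimingConfig:
        return SortTimingConfig(**self.model_dump())


class SimulationModel(BaseModel):
    rate: float = Field(50.0, gt=0, description="mean event rate, events/s")
    r: float = Field(0.6, ge=0, le=1)
    duration: float = Field(2.0, gt=0, description="acquisition length, s")


class SegmentationModel(BaseModel):
    gaussian_sigma: float = Field(1.0, gt=0)
    tophat_radius: int = Field(15, gt=0)
    canny_sigma: float = Field(1.0, gt=0)
    canny_low_frac: float = Field(0.1, gt=0, lt=1)
    canny_high_frac: float = Field(0.3, gt=0, lt=1)
    close_radius: int = Field(2, gt=0)
    spur_neighbor_min: int = Field(5, ge=0, le=8)
    min_area_px: int = Field(20, ge=0)
    margin_rows: int = Field(5, gt=0)

    def build(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class GateModel(BaseModel):
    x_feature: str = "PS_density"
    y_feature: str = "PMMA_density"
    type: Literal["rectangle", "polygon"] = "rectangle"
    rectangle: Optional[tuple[float, float, float, float]] = (-2.0, 2.0, 4.0, 40.0)
    vertices: Optional[list[tuple[float, float]]] = None

    @model_validator(mode="after")
    def _check_region(self) -> "GateModel":
        if self.type == "rectangle" and self.rectangle is None:
            raise ValueError("rectangle gate requires 'rectangle'")
        if self.type == "polygon" and (self.vertices is None or len(self.vertices) < 3):
            raise ValueError("polygon gate requires >= 3 vertices")
        return self

    def build(self) -> Gate:
        region = self.rectangle if self.type == "rectangle" else tuple(self.vertices)
        return Gate(self.x_feature, self.y_feature, tuple(region))


class RunConfig(BaseModel):
    """Schema-validated configuration for a virtual sorting run."""

    acquisition: AcquisitionModel = AcquisitionModel()
    timing: TimingModel = TimingModel()
    simulation: SimulationModel = SimulationModel()
    segmentation: SegmentationModel = SegmentationModel()
    gate: GateModel = GateModel()
    basis_path: Optional[str] = None
    fsc_threshold: float = Field(1.0, gt=0)
    refractory: float = Field(2e-4, ge=0)
    seed: int = Field(0, ge=0)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))
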