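"""Run configuration: one YAML file describing every pipeline stage.

Unknown keys are rejected (typo safety) and the config round-trips through
YAML without loss.  Defaults are the assay's conventional values: 10% tile
overlap, 20 background sample points, the 50-cell clone threshold and 200
seeded cells per well.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    params: dict = Field(default_factory=dict)   # SimParams overrides


class StitchConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    overlap_frac: float = 0.10
    max_shift: int = 20
    downsample: int = 4
    n_background_points: int = 20
    background_patch: int = 15


class SegmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_object_px: int = 9
    h_min: float = 3.0
    reference_channel: Optional[str] = None


class ClassifyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    model_path: Optional[str] = None      # JSON model; None -> rule-based
    on_fraction: float = 0.25


class CloneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    eps: Optional[float] = None           # None -> automatic k-distance knee
    min_samples: int = 3
    color_constrained: bool = True


class SurvivalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seeded_cells: int = 200
    min_cells_per_clone: int = 50
    small_intensity_max: float = 0.5
    large_intensity_range: tuple[float, float] = (3.0, 10.0)
    small_area_max: float = 0.5
    large_area_range: tuple[float, float] = (2.0, 4.0)
    low_roundness_max: float = 0.5
    low_circularity_max: float = 0.9
    dna_histogram: bool = False


class ScreenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    treatment_map: Optional[str] = None
    k: int = 3


class PipelineConfig(BaseModel):
    """Full pipeline configuration for one run."""

    model_config = ConfigDict(extra="forbid")

    input_dir: Optional[str] = None       # tile TIFFs (or None when simulating)
    output_dir: str = "clonoscope_out"
    channels: tuple[str, ...] = ("r", "g", "b")
    seed: int = 0
    version: str = "1"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    stitch: StitchConfig = Field(default_factory=StitchConfig)
    segment: SegmentConfig = Field(default_factory=SegmentConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)
    clones: CloneConfig = Field(default_factory=CloneConfig)
    survival: SurvivalConfig = Field(default_factory=SurvivalConfig)
    screen: ScreenConfig = Field(default_factory=ScreenConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)
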