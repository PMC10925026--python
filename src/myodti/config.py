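"""Validated pipeline configuration.

All tunables of the end-to-end analysis live in one pydantic model,
loadable from YAML.  Unknown keys are rejected so a typo fails fast instead
of silently running with a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_StrictModel):
    manifest: Path
    loading_table: Path
    output_dir: Path = Path("myodti_out")


class PreprocessingConfig(_StrictModel):
    background_radius: int = 50  # px, disk radius of the opening
    quantize_8bit: bool = False


class SegmentationConfig(_StrictModel):
    min_area: float = 30.0  # px^2
    peak_min_distance: int = 4  # px, suited to ~8 px fiber radius
    smoothing_sigma: float = 1.5  # px


class LocalizationConfig(_StrictModel):
    n_null: int = 199  # screening draws per section
    n_null_refine: int = 2999  # refinement draws for each sample's best section
    alpha_loc: float = Field(0.05, gt=0, lt=1)
    correction: str | None = "sidak-study"


class FitConfig(_StrictModel):
    starts: int = 16
    cell_death_c_bounds: tuple[float, float] = (0.0, 6.0)
    no_damage_c_bounds: tuple[float, float] = (3.7, 20.0)


class ExclusionConfig(_StrictModel):
    sample_id: str
    reason: str = ""


class PipelineConfig(_StrictModel):
    """Full configuration of one analysis run."""

    paths: PathsConfig
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    localization: LocalizationConfig = LocalizationConfig()
    fit: FitConfig = FitConfig()
    #: (external kPa, internal kPa) pairs for the internal-stress calibration
    calibration_pairs: list[tuple[float, float]] = [(5.0, 3.4), (103.0, 69.1)]
    exclusions: list[ExclusionConfig] = []
    #: disk ROI radius around the indent center, px; None counts the whole section
    indent_radius: float | None = None
    seed: int = 0
    expected_sections: int = 6

    @field_validator("calibration_pairs")
    @classmethod
    def _at_least_two(cls, v):
        if len(v) < 2:
            raise ValueError("need at least two calibration pairs")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        """Stable digest of the full configuration, for run manifests."""
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
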