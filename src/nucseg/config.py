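"""Validated pipeline configuration (YAML/JSON), unknown keys rejected."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classify import SplitSpec
from .features import FeatureConfig
from .preprocess import PreprocessConfig
from .refine import RefineConfig
from .segment import TwoPassConfig
from .watershed import WatershedConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessSection(_Section):
    background_radius_um: float = 0.0
    filter: str = "none"
    filter_radius_um: float = 0.0

    def build(self) -> PreprocessConfig:
        return PreprocessConfig(**self.model_dump())


class SegmentSection(_Section):
    global_method: str = "triangle"
    local_method: str = "mean"
    dilation_um: float = 3.0
    min_seed_area_um2: float = 20.0

    def build(self) -> TwoPassConfig:
        return TwoPassConfig(**self.model_dump())


class RefineSection(_Section):
    enabled: bool = True
    half_width_um: float = 1.0
    max_iterations: int = 5
    convergence_tol_px: float = 0.5

    def build(self) -> RefineConfig:
        d = self.model_dump()
        d.pop("enabled")
        return RefineConfig(**d)


class WatershedSection(_Section):
    enabled: bool = True
    min_area_um2: float = 20.0
    decay_cutoff: float = 0.75
    profile_halfwidth_um: float = 1.5

    def build(self) -> WatershedConfig:
        d = self.model_dump()
        d.pop("enabled")
        return WatershedConfig(**d)


class FeatureSection(_Section):
    n_harmonics: int = 20
    curvature_step_um: float = 0.5
    glcm_levels: int = 64
    glcm_distance_px: int = 1
    include_border: bool = False

    def build(self) -> FeatureConfig:
        return FeatureConfig(**self.model_dump())


class ClassifySection(_Section):
    model: str = "svm_rbf"
    test_fraction: float = 1 / 3
    cv_folds: int = 10

    def build(self, seed: int) -> SplitSpec:
        return SplitSpec(test_fraction=self.test_fraction,
                         cv_folds=self.cv_folds, seed=seed)


class PipelineConfig(_Section):
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    segment: SegmentSection = Field(default_factory=SegmentSection)
    refine: RefineSection = Field(default_factory=RefineSection)
    watershed: WatershedSection = Field(default_factory=WatershedSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    classify: ClassifySection = Field(default_factory=ClassifySection)
    pixel_size_um: float | None = None
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
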