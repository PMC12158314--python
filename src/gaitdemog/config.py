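"""Schema-validated run configuration (YAML) for the end-to-end pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WaveletConfig(_Strict):
    family: str = "db4"
    level: int = 3
    threshold: str = "soft"


class PreprocessConfig(_Strict):
    window_seconds: float = 3.0
    overlap: float = 0.5
    denoise: bool = True
    denoise_first: bool = True
    wavelet: WaveletConfig = Field(default_factory=WaveletConfig)


class SimulateConfig(_Strict):
    n_subjects: int = 200
    sex_ratio: float = 389 / 744
    recording_duration: float = 15.0
    sampling_rate: float = 100.0
    age_distribution: list[tuple[tuple[int, int], float]] | None = None


class FeatureConfig(_Strict):
    peak_min_separation_s: float = 0.2
    welch_nperseg: int = 128
    welch_overlap: float = 0.5


class SplitConfig(_Strict):
    train_fraction: float = 0.7
    by_subject: bool = True


class SelectConfig(_Strict):
    n_keep: int = 30
    step: int = 1


class ModelsConfig(_Strict):
    classifiers: list[str] = Field(default_factory=lambda: ["svc", "knn", "rf"])
    regressors: list[str] = Field(default_factory=lambda: ["knn", "svr", "lightgbm"])
    stacking: bool = True


class EvaluateConfig(_Strict):
    by_age_group: bool = True
    by_position: bool = False


class RunConfig(_Strict):
    """Top-level pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "runs/demo"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    select: SelectConfig = Field(default_factory=SelectConfig)
    models: ModelsConfig = Field(default_factory=ModelsConfig)
    evaluate: EvaluateConfig = Field(default_factory=EvaluateConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid run configuration {path}: {exc}") from exc
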