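"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    n_per_class: int = 20
    duration_min: float = 20.0
    contrast: str = "default"  # or "zero"
    seed: int = 0


class PreprocessingSection(_Strict):
    max_interp_s: float = 15.0
    quality_cap: float = 0.10
    valid_lo_bpm: float = 50.0
    valid_hi_bpm: float = 220.0


class FeaturesSection(_Strict):
    apen_m: int = 2
    apen_r_factor: float = 0.2


class ImagingSection(_Strict):
    encoders: list[str] = Field(default_factory=lambda: ["GADF", "PS", "PSP"])


class ModelSection(_Strict):
    kind: str = "combined"  # mlp | cnn | combined
    fusion: str = "softmax"  # or penultimate


class TrainingSection(_Strict):
    learning_rate: float = 1e-4
    decay: float = 1e-4 / 200
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 2
    train_fraction: float = 0.8
    val_fraction: float = 0.1
    seed: int = 0


class EvaluationSection(_Strict):
    repetitions: int = 30
    test_fraction: float = 0.2
    alpha: float = 0.01
    seed: int = 0


class PipelineConfig(_Strict):
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocessing: PreprocessingSection = Field(default_factory=PreprocessingSection)
    features: FeaturesSection = Field(default_factory=FeaturesSection)
    imaging: ImagingSection = Field(default_factory=ImagingSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)

    @classmethod
    def load(cls, path: str | Path | None) -> "PipelineConfig":
        if path is None:
            return cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
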