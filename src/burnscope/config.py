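"""Pipeline configuration: a validated YAML-backed schema.

Unknown keys are rejected so that typos in a config file fail loudly instead
of silently running with defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GaussianConfig(_Strict):
    """Low-pass filter applied to each of the L, u, v planes."""
    size: int = 5
    sigma: float = 1.5

    @field_validator("size")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v < 3 or v % 2 == 0:
            raise ValueError("kernel size must be an odd integer >= 3")
        return v

    @field_validator("sigma")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("sigma must be positive")
        return v


class DceConfig(_Strict):
    """Contrast-enhancement operator and its kinetic grounding."""
    gain: float = Field(0.5, ge=0.0)
    gamma: float = Field(0.8, gt=0.0, le=1.0)
    eval_time: float = Field(2.0, gt=0.0)    # minutes
    ktrans: float = Field(0.2, ge=0.0)       # per minute
    ve: float = Field(0.4, gt=0.0, le=1.0)   # EES volume fraction


class AcicaConfig(_Strict):
    ncluster: int = Field(4, ge=1)
    fuzzifier: float = Field(2.0, gt=1.0)
    tol: float = Field(1e-5, gt=0.0)
    max_iter: int = Field(300, ge=1)
    seed: int = 0
    use_unmixing: bool = False


class RrConfig(_Strict):
    zth: int = Field(10, ge=0, lt=255)
    dth: float = Field(16.0, gt=0.0)
    qlevels: int = Field(64, ge=8, le=256)
    th: float | None = Field(None, gt=0.0)   # labeling similarity threshold; dth if unset


class GlcmConfig(_Strict):
    levels: int = Field(8, ge=2)
    distance: int = Field(1, ge=1)


class ModelConfig(_Strict):
    kind: str = "cnn"
    epochs: int = Field(50, ge=1)
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 42
    input_size: int = Field(224, ge=8)
    batch_size: int = Field(8, ge=1)
    learning_rate: float = Field(1e-3, gt=0.0)
    augment: bool = True

    @field_validator("kind")
    @classmethod
    def _kind(cls, v: str) -> str:
        if v not in {"cnn", "fnn", "rnn"}:
            raise ValueError("model kind must be one of cnn/fnn/rnn")
        return v

    @field_validator("split_fractions")
    @classmethod
    def _fractions(cls, v):
        if len(v) != 3 or any(f < 0 for f in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("split fractions must be three nonnegative numbers summing to 1")
        return tuple(v)


class PathsConfig(_Strict):
    out_dir: str = "."


class PipelineConfig(_Strict):
    """Full configuration of the burn-analysis pipeline."""
    gaussian: GaussianConfig = GaussianConfig()
    dce: DceConfig = DceConfig()
    acica: AcicaConfig = AcicaConfig()
    rr: RrConfig = RrConfig()
    glcm: GlcmConfig = GlcmConfig()
    model: ModelConfig = ModelConfig()
    paths: PathsConfig = PathsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
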