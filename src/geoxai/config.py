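"""Run configuration: a single validated schema for the whole pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config"]


class LatticeConfig(BaseModel):
    nrows: int = 20
    ncols: int = 20
    cell_size: float = 1.0


class SimulateConfig(BaseModel):
    spatial_range: float = 4.0


class WeightsConfig(BaseModel):
    rule: str = "queen"  # rook | queen; or set band to use a distance band
    band: float | None = None

    @field_validator("rule")
    @classmethod
    def _rule_ok(cls, v: str) -> str:
        if v not in ("rook", "queen"):
            raise ValueError("rule must be 'rook' or 'queen'")
        return v


class SplitConfig(BaseModel):
    fractions: list[float] = Field(default=[0.70, 0.15, 0.15])

    @field_validator("fractions")
    @classmethod
    def _fractions_ok(cls, v: list[float]) -> list[float]:
        if len(v) != 3 or any(f <= 0 for f in v):
            raise ValueError("need three positive fractions (train, valid, test)")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(v)}")
        return v


class TrainConfig(BaseModel):
    grids: str = "small"  # small | default
    folds: int = 5
    mode: str = "all_models"  # all_models | best_of_family
    include_mlp: bool = False

    @field_validator("mode")
    @classmethod
    def _mode_ok(cls, v: str) -> str:
        if v not in ("all_models", "best_of_family"):
            raise ValueError("mode must be 'all_models' or 'best_of_family'")
        return v


class ExplainConfig(BaseModel):
    n_repeats: int = 5
    top_features: int = 6
    profile_points: int = 21
    al_intervals: int = 10
    n_ref: int = 200
    lmi_factor: str = "smoking"
    lmi_permutations: int = 199


class RunConfig(BaseModel):
    seed: int = 0
    outdir: str = "runs/demo"
    lattice: LatticeConfig = Field(default_factory=LatticeConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    weights: WeightsConfig = Field(default_factory=WeightsConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    explain: ExplainConfig = Field(default_factory=ExplainConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
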