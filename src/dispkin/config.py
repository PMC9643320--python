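"""Run configuration: schema-validated YAML/JSON for the CLI."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class OptimizerSettings(BaseModel):
    weighting: str = "duration"
    tracer_solver: str = "expm"
    max_nfev: int = 400
    k1d_starts_uL: list[float] = Field(default=[1.0, 10.0, 100.0])

    @field_validator("weighting")
    @classmethod
    def _weighting(cls, v):
        if v not in ("duration", "uniform", "decay", "ivar"):
            raise ValueError(
                "weighting must be one of duration, uniform, decay, ivar")
        return v

    @field_validator("tracer_solver")
    @classmethod
    def _solver(cls, v):
        if v not in ("expm", "lsoda"):
            raise ValueError("tracer_solver must be 'expm' or 'lsoda'")
        return v


class RunConfig(BaseModel):
    """Configuration for `dispkin fit` / `bounds` / `sensitivity`.

    Defaults reproduce the 5-parameter analysis setup.
    """

    datasets: list[str]
    regions: list[str] = Field(default=["putamen", "frontal", "cerebellum"])
    model: str = "5p"
    fixed_overrides: dict[str, float] = Field(default_factory=dict)
    optimizer: OptimizerSettings = Field(default_factory=OptimizerSettings)
    alpha: float = 0.05
    bound_grid_uL: dict[str, list[float]] = Field(
        default={"BRV": [30, 40, 50, 60, 70, 80, 90, 100],
                 "LEV": [5, 6, 7, 8, 9, 10]}
    )
    seed: int = 0
    out_dir: str = "results"

    @field_validator("datasets")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("at least one dataset path is required")
        return v


def load_run_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    return RunConfig.model_validate(raw)
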