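"""Run configuration: one JSON file, schema-validated before any computation."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .synthetic_library import SimConfig

__all__ = ["RunConfig", "ScreenOptions", "FitOptions", "load_config"]


class ScreenOptions(BaseModel):
    """Pipeline thresholds (see screen_pipeline for semantics)."""

    model_config = ConfigDict(extra="forbid")

    k_extremes: int = 48
    od_floor: float = 0.05
    gc_edges: list[float] = Field(default=[0.2, 0.32, 0.44, 0.56, 0.68, 0.8])


class FitOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pooled: bool = False


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    outdir: str = "results"
    sim: dict = Field(default_factory=dict)
    screen: ScreenOptions = Field(default_factory=ScreenOptions)
    fit: FitOptions = Field(default_factory=FitOptions)

    def sim_config(self) -> SimConfig:
        d = dict(self.sim)
        d["seed"] = self.seed
        return SimConfig.from_dict(d)


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        return RunConfig.model_validate(json.load(fh))
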