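"""Schema-validated run configuration for the command-line pipeline.

The YAML config mirrors the pipeline stages; unknown keys are rejected
up front so typos fail before any stage runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSettings(_Strict):
    n_participants: int = Field(120, ge=1)
    samples_per_participant: int = Field(10, ge=1)
    trial_duration: float = Field(10.0, gt=0)
    frame_rate: float = Field(30.0, gt=0)
    sensor_rate: float = Field(8.0, gt=0)
    face_drop_rate: float = Field(0.02, ge=0, lt=1)


class ForestSettings(_Strict):
    n_trees: int = Field(30, ge=1)
    max_depth: int | None = Field(None, ge=1)
    min_samples_split: int = Field(2, ge=2)
    min_samples_leaf: int = Field(1, ge=1)


class FacePrepSettings(_Strict):
    clahe_clip: float = Field(0.02, gt=0, le=1)
    clahe_grid: tuple[int, int] = (8, 8)
    section_margin: float = Field(0.10, ge=0, le=1)


class TrainFerSettings(_Strict):
    epochs: int = Field(50, ge=1)
    batch_size: int = Field(128, ge=1)
    dropout_rate: float = Field(0.4, ge=0, lt=1)
    learning_rate: float = Field(1e-3, gt=0)
    toy_architecture: bool = True


class RunConfig(_Strict):
    """Top-level configuration; every stage reads its own section."""

    seed: int = 0
    simulate: SimulateSettings = SimulateSettings()
    forest: ForestSettings = ForestSettings()
    faceprep: FacePrepSettings = FacePrepSettings()
    train_fer: TrainFerSettings = TrainFerSettings()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; defaults when *path* is None."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
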