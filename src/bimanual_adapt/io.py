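"""Dataset and configuration I/O.

Datasets are exchanged as tidy long-format delimited tables (CSV, UTF-8,
header row): one row per (trial, hand, sample) with columns

    participant, group, trial, phase, block, condition, field_type,
    hand, t_ms, x, y, vx, vy, fx, fy

Force columns hold the measured left-hand force and are empty for
``hand == "right"`` rows.  Floats are written with full round-trip
precision, so write -> read reproduces a dataset exactly.  Run
configurations serialize to YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .synth import (FieldParams, KinematicsConfig, LearnerConfig, PlantConfig,
                    TrialRecord)

SCHEMA_VERSION = 1

DATASET_COLUMNS = [
    "participant", "group", "trial", "phase", "block", "condition",
    "field_type", "hand", "t_ms", "x", "y", "vx", "vy", "fx", "fy",
]


class SchemaError(ValueError):
    """A dataset file does not match the expected tidy schema."""


def dataset_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten TrialRecords into the tidy long-format table."""
    chunks = []
    for t in trials:
        n = t.n_samples
        labels = dict(participant=t.participant, group=t.group, trial=t.trial,
                      phase=t.phase, block=t.block, condition=t.condition,
                      field_type=t.field_type)
        chunks.append(pd.DataFrame({
            **labels, "hand": "left", "t_ms": t.t_ms,
            "x": t.left_pos[:, 0], "y": t.left_pos[:, 1],
            "vx": t.left_vel[:, 0], "vy": t.left_vel[:, 1],
            "fx": t.force[:, 0], "fy": t.force[:, 1],
        }))
        chunks.append(pd.DataFrame({
            **labels, "hand": "right", "t_ms": t.t_ms,
            "x": t.right_pos[:, 0], "y": t.right_pos[:, 1],
            "vx": t.right_vel[:, 0], "vy": t.right_vel[:, 1],
            "fx": np.nan, "fy": np.nan,
        }))
    if not chunks:
        return pd.DataFrame(columns=DATASET_COLUMNS)
    return pd.concat(chunks, ignore_index=True)[DATASET_COLUMNS]


def frame_to_dataset(frame: pd.DataFrame) -> list[TrialRecord]:
    """Reassemble TrialRecords from a tidy long-format table."""
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"dataset table is missing columns: {missing}")
    trials: list[TrialRecord] = []
    for (participant, trial), g in frame.groupby(["participant", "trial"],
                                                 sort=True):
        left = g[g["hand"] == "left"].sort_values("t_ms")
        right = g[g["hand"] == "right"].sort_values("t_ms")
        if len(left) != len(right) or len(left) == 0:
            raise SchemaError(
                f"trial {trial} of participant {participant}: left/right "
                "sample counts differ or are empty")
        first = left.iloc[0]
        trials.append(TrialRecord(
            participant=int(participant), group=str(first["group"]),
            trial=int(trial), phase=str(first["phase"]),
            block=int(first["block"]), condition=str(first["condition"]),
            field_type=str(first["field_type"]),
            t_ms=left["t_ms"].to_numpy(float),
            left_pos=left[["x", "y"]].to_numpy(float),
            left_vel=left[["vx", "vy"]].to_numpy(float),
            right_pos=right[["x", "y"]].to_numpy(float),
            right_vel=right[["vx", "vy"]].to_numpy(float),
            force=left[["fx", "fy"]].to_numpy(float),
        ))
    return trials


def write_dataset(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write a dataset as a tidy CSV (lossless for float64 values)."""
    # %.17g guarantees exact float64 round-trip through text
    dataset_to_frame(trials).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> list[TrialRecord]:
    """Read a tidy CSV dataset back into TrialRecords."""
    try:
        # keep_default_na: the "null" field type must stay a string;
        # empty cells (right-hand force columns) still read as NaN
        frame = pd.read_csv(path, float_precision="round_trip",
                            keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty or not a CSV table") from exc
    return frame_to_dataset(frame)


@dataclass
class AnalysisOptions:
    """Knobs of the analysis pipeline that the original method leaves open."""

    onset_threshold: float = 0.05       # fraction of peak speed
    peak_force_half_window_ms: int = 10  # "20 ms around peak velocity"
    fc_intercept: bool = False
    average_by_condition: bool = True    # fit on condition-averaged profiles
    fit_weight_trajectory: bool = True
    weight_block_size: int = 96

    def __post_init__(self) -> None:
        if not (0 < self.onset_threshold < 1):
            raise ValueError("onset_threshold must lie in (0, 1)")
        if self.peak_force_half_window_ms <= 0 or self.weight_block_size <= 0:
            raise ValueError("window sizes must be positive")


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate-and-analyze run."""

    seed: int = 0
    n_participants_per_group: int = 8
    groups: tuple[str, ...] = ("evident", "ambiguous")
    omega_true: dict = dc_field(default_factory=lambda: {"evident": 0.9,
                                                         "ambiguous": 0.4})
    learner: LearnerConfig = dc_field(default_factory=LearnerConfig)
    kinematics: KinematicsConfig = dc_field(default_factory=KinematicsConfig)
    field: FieldParams = dc_field(default_factory=FieldParams)
    plant_enabled: bool = False
    plant: PlantConfig = dc_field(default_factory=PlantConfig)
    analysis: AnalysisOptions = dc_field(default_factory=AnalysisOptions)
    output_dir: str = "results"
    write_dataset: bool = False  # full time-series tables are large

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in [("learner", LearnerConfig),
                         ("kinematics", KinematicsConfig),
                         ("field", FieldParams), ("plant", PlantConfig),
                         ("analysis", AnalysisOptions)]:
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
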