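"""Task conditions and trial schedules for the bimanual curl-field paradigm.

The experiment crosses three left-hand speed classes with three right-hand
speed classes (nine bimanual conditions) and adds three unimanual
conditions in which only the left hand moves.  Speed classes tie reach
distance to desired peak speed so that every reach shares one nominal
movement time.  Two training regimes exist: the *evident* group trains on
conditions with mismatched hand speeds (the dependence of the left-hand
force on right-hand velocity is observable within a trial), the
*ambiguous* group trains on matched-speed conditions (the dependence is
hidden behind motor variability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

SpeedClassName = Literal["slow", "medium", "fast"]
Phase = Literal["baseline", "exposure", "generalization"]
FieldType = Literal["null", "force_field", "clamp"]

PHASES: tuple[Phase, ...] = ("baseline", "exposure", "generalization")
FIELD_TYPES: tuple[FieldType, ...] = ("null", "force_field", "clamp")


@dataclass(frozen=True)
class SpeedClass:
    """A reach template: distance and desired peak speed (SI units).

    Distances of 15/20/25 cm are paired with desired peak speeds of
    45/60/75 cm/s so that distance and speed are jointly monotone and the
    nominal movement time (700 ms) is shared across classes.  Compliance
    is judged against ``desired_peak * (1 ± tolerance)``.
    """

    name: SpeedClassName
    distance: float          # m
    desired_peak: float      # m/s
    tolerance: float = 0.10  # fraction of desired_peak
    movement_time: float = 0.700  # s, nominal (instructed) movement time

    def __post_init__(self) -> None:
        if self.distance <= 0 or self.desired_peak <= 0:
            raise ValueError("distance and desired_peak must be positive")

    @property
    def band(self) -> tuple[float, float]:
        """Compliance band for peak speed, in m/s."""
        return (self.desired_peak * (1 - self.tolerance),
                self.desired_peak * (1 + self.tolerance))


SPEED_CLASSES: dict[SpeedClassName, SpeedClass] = {
    "slow": SpeedClass("slow", 0.15, 0.45),
    "medium": SpeedClass("medium", 0.20, 0.60),
    "fast": SpeedClass("fast", 0.25, 0.75),
}

_CLASS_ORDER: tuple[SpeedClassName, ...] = ("slow", "medium", "fast")
_CLASS_LETTER = {"slow": "s", "medium": "m", "fast": "f"}


@dataclass(frozen=True)
class Condition:
    """One of the twelve task conditions.

    ``left_class`` and ``right_class`` name the speed class of each hand.
    ``right_class`` is ``None`` for unimanual conditions (left hand moves,
    right hand stationary); the left hand always moves.
    """

    left_class: SpeedClassName
    right_class: Optional[SpeedClassName]

    def __post_init__(self) -> None:
        if self.left_class not in SPEED_CLASSES:
            raise ValueError(f"unknown left speed class {self.left_class!r}")
        if self.right_class is not None and self.right_class not in SPEED_CLASSES:
            raise ValueError(f"unknown right speed class {self.right_class!r}")

    @property
    def bimanual(self) -> bool:
        return self.right_class is not None

    @property
    def label(self) -> str:
        """Compact name: ``b_<left><right>`` bimanual, ``u_<left>`` unimanual."""
        if self.bimanual:
            return f"b_{_CLASS_LETTER[self.left_class]}{_CLASS_LETTER[self.right_class]}"
        return f"u_{_CLASS_LETTER[self.left_class]}"

    @property
    def left(self) -> SpeedClass:
        return SPEED_CLASSES[self.left_class]

    @property
    def right(self) -> Optional[SpeedClass]:
        return None if self.right_class is None else SPEED_CLASSES[self.right_class]


def build_condition_grid() -> list[Condition]:
    """Enumerate the 12 task conditions in deterministic order.

    Bimanual conditions come first, row-major by left then right speed
    class (slow→fast), followed by the three unimanual conditions
    slow→fast.
    """
    grid = [Condition(lc, rc) for lc in _CLASS_ORDER for rc in _CLASS_ORDER]
    grid += [Condition(lc, None) for lc in _CLASS_ORDER]
    return grid


CONDITIONS: dict[str, Condition] = {c.label: c for c in build_condition_grid()}

#: trained condition labels per group; the evident group sees mismatched
#: hand speeds plus the matched middle condition, the ambiguous group only
#: matched speeds.
TRAINED_CONDITIONS: dict[str, tuple[str, str, str]] = {
    "evident": ("b_sf", "b_mm", "b_fs"),
    "ambiguous": ("b_ss", "b_mm", "b_ff"),
}


@dataclass(frozen=True)
class GroupDesign:
    """Training regime: which three bimanual conditions carry the field."""

    group: Literal["evident", "ambiguous"]
    trained_conditions: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.group not in TRAINED_CONDITIONS:
            raise ValueError(
                f"unknown group {self.group!r}; expected 'evident' or 'ambiguous'")
        if not self.trained_conditions:
            object.__setattr__(self, "trained_conditions",
                               TRAINED_CONDITIONS[self.group])
        for label in self.trained_conditions:
            cond = CONDITIONS.get(label)
            if cond is None or not cond.bimanual:
                raise ValueError(f"trained condition {label!r} must be bimanual")


@dataclass(frozen=True)
class ScheduleEntry:
    """One row of the experiment schedule."""

    trial: int          # 1-based across the whole experiment
    phase: Phase
    block: int          # 1-based within phase
    condition: str      # condition label
    field_type: FieldType


# Per-block recipes.  Baseline blocks 1-5 rotate all 12 conditions, the
# last baseline block previews the trained-condition mixture used during
# exposure (but still in the null field).
_N_BASELINE_BLOCKS = 6
_N_EXPOSURE_BLOCKS = 20
_N_GENERALIZATION_BLOCKS = 20
BLOCK_SIZE = 48


def _baseline_block(block: int, trained: tuple[str, ...]) -> list[tuple[str, FieldType]]:
    if block <= 5:
        out: list[tuple[str, FieldType]] = []
        for cond in CONDITIONS:
            out += [(cond, "null")] * 3 + [(cond, "clamp")]
        return out
    out = []
    for cond in trained:
        out += [(cond, "null")] * 14 + [(cond, "clamp")] * 2
    return out


def _exposure_block(trained: tuple[str, ...]) -> list[tuple[str, FieldType]]:
    out: list[tuple[str, FieldType]] = []
    for cond in trained:
        out += [(cond, "force_field")] * 14 + [(cond, "clamp")] * 2
    return out


def _generalization_block(trained: tuple[str, ...]) -> list[tuple[str, FieldType]]:
    out: list[tuple[str, FieldType]] = []
    for cond in trained:
        out += [(cond, "force_field")] * 12
    out += [(cond, "clamp") for cond in CONDITIONS]
    return out


def build_schedule(group_design: GroupDesign | str, seed: int) -> list[ScheduleEntry]:
    """Build the full 2208-trial schedule for one participant.

    Phases: baseline (6 blocks), exposure (20 blocks) and generalization
    (20 blocks), each block of 48 trials.  Trial order within every block
    is an unconstrained uniform shuffle drawn from a seeded, splittable
    generator, so equal seeds yield identical schedules.  No constraint
    prevents consecutive clamp trials (none is imposed by the design).

    Parameters
    ----------
    group_design : GroupDesign or str
        The training regime, or a group name (``"evident"`` /
        ``"ambiguous"``).
    seed : int
        Non-negative seed for the within-block shuffles.
    """
    if isinstance(group_design, str):
        group_design = GroupDesign(group_design)
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    trained = group_design.trained_conditions

    blocks: list[tuple[Phase, int, list[tuple[str, FieldType]]]] = []
    for b in range(1, _N_BASELINE_BLOCKS + 1):
        blocks.append(("baseline", b, _baseline_block(b, trained)))
    for b in range(1, _N_EXPOSURE_BLOCKS + 1):
        blocks.append(("exposure", b, _exposure_block(trained)))
    for b in range(1, _N_GENERALIZATION_BLOCKS + 1):
        blocks.append(("generalization", b, _generalization_block(trained)))

    child_seeds = np.random.SeedSequence(seed).spawn(len(blocks))
    schedule: list[ScheduleEntry] = []
    trial = 1
    for (phase, block, entries), child in zip(blocks, child_seeds):
        if len(entries) != BLOCK_SIZE:  # defensive: recipe must be exact
            raise AssertionError(f"block recipe produced {len(entries)} trials")
        rng = np.random.default_rng(child)
        order = rng.permutation(len(entries))
        for i in order:
            cond, ftype = entries[i]
            schedule.append(ScheduleEntry(trial, phase, block, cond, ftype))
            trial += 1
    return schedule


def schedule_to_frame(schedule: list[ScheduleEntry]) -> pd.DataFrame:
    """Schedule as a tidy table (trial, phase, block, condition, field_type)."""
    return pd.DataFrame(
        {
            "trial": [e.trial for e in schedule],
            "phase": [e.phase for e in schedule],
            "block": [e.block for e in schedule],
            "condition": [e.condition for e in schedule],
            "field_type": [e.field_type for e in schedule],
        }
    )
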