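"""Daily training prescription and session modulation.

Each training morning the 7-day rolling average is compared to the baseline
SWC windows:

* inside SWC1 (±0.5 SD)            -> FULL: train as programmed;
* between SWC1 and SWC2 (±1 SD)    -> REDUCED: the scheduled session's
  repetitions and external load are both cut by 25%;
* outside SWC2                     -> RECOVERY: replace the session with a
  fixed 20-minute low-intensity active-recovery session (walking, light
  mobility, below 50% heart-rate reserve).

Deviations above and below baseline are treated symmetrically. When the
rolling average is undefined (too few readings), the previous day's decision
context is carried forward and flagged.

A "day at high intensity" (DHI) is an attended session executed at full,
unmodulated intensity; attended sessions of a predetermined (non-guided) arm
always count.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping

from .calibration import BaselineProfile, RollingState
from .prescriber import FULL, RECOVERY, REDUCED, SEVERITY, classify_deviation

__all__ = [
    "TrainingDecision",
    "ExerciseBlock",
    "Session",
    "ModulatedSession",
    "ACTIVE_RECOVERY",
    "decide",
    "modulate_session",
    "classify_dhi",
    "FULL",
    "REDUCED",
    "RECOVERY",
    "SEVERITY",
]

#: volume/load multiplier applied to a REDUCED session
REDUCTION = 0.75


@dataclasses.dataclass(frozen=True)
class TrainingDecision:
    """The day's prescription with the inputs that produced it."""

    value: str  # FULL | REDUCED | RECOVERY
    deviation: float | None  # hrv7 - baseline mean, score units (signed)
    hrv7: float | None
    profile: BaselineProfile | None
    flagged: bool = False  # True when carried forward under missing data


@dataclasses.dataclass(frozen=True)
class ExerciseBlock:
    """One movement prescription; load 0 marks bodyweight work."""

    movement: str
    reps: int
    load_kg: float = 0.0

    def __post_init__(self) -> None:
        if self.reps < 0 or self.load_kg < 0:
            raise ValueError("repetitions and load must be non-negative")


@dataclasses.dataclass(frozen=True)
class Session:
    blocks: tuple[ExerciseBlock, ...]
    duration_min: float = 60.0
    intensity_tag: str = "HIGH"


ACTIVE_RECOVERY = Session(
    blocks=(ExerciseBlock("active recovery: walking and light mobility "
                          "(below 50% heart-rate reserve)", 0, 0.0),),
    duration_min=20.0,
    intensity_tag="RECOVERY",
)


@dataclasses.dataclass(frozen=True)
class ModulatedSession:
    session: Session
    decision_value: str
    volume_multiplier: float


def decide(state: RollingState, profile: BaselineProfile,
           last: TrainingDecision | None = None) -> TrainingDecision:
    """Prescription for one training day from the rolling state and profile.

    With an undefined rolling average the last decision context is carried
    forward (flagged); with no prior context the mildest prescription (FULL)
    is issued, flagged.
    """
    if state.hrv7 is None:
        if last is not None:
            return dataclasses.replace(last, flagged=True)
        return TrainingDecision(FULL, None, None, profile, flagged=True)
    deviation = state.hrv7 - profile.mean
    value = classify_deviation(deviation, profile.sd, degenerate=profile.degenerate)
    return TrainingDecision(str(value), deviation, state.hrv7, profile)


def _round_half_down(x: float) -> int:
    """Nearest integer, ties toward zero-ward (7.5 -> 7); conservative volume."""
    return int(math.ceil(x - 0.5))


def modulate_session(template: Session,
                     decision: TrainingDecision | str) -> ModulatedSession:
    """Apply the day's prescription to the scheduled session.

    FULL returns the template unchanged; REDUCED multiplies every block's
    repetitions (rounded half-down, minimum 1 when the block had any) and load
    by 0.75; RECOVERY substitutes the fixed 20-minute active-recovery session.
    """
    value = decision.value if isinstance(decision, TrainingDecision) else decision
    if value == FULL:
        return ModulatedSession(template, FULL, 1.0)
    if value == REDUCED:
        blocks = tuple(
            dataclasses.replace(
                b,
                reps=max(1, _round_half_down(REDUCTION * b.reps)) if b.reps >= 1 else 0,
                load_kg=REDUCTION * b.load_kg,
            )
            for b in template.blocks
        )
        reduced = dataclasses.replace(template, blocks=blocks, intensity_tag="REDUCED")
        return ModulatedSession(reduced, REDUCED, REDUCTION)
    if value == RECOVERY:
        return ModulatedSession(ACTIVE_RECOVERY, RECOVERY, 0.0)
    raise ValueError(f"unknown decision value {value!r}")


def classify_dhi(record: Mapping) -> bool:
    """True iff the session counts as a day at high intensity.

    ``record`` needs ``attended`` (bool) and ``decision`` (FULL | REDUCED |
    RECOVERY for a guided arm; None or "NA" for a predetermined arm, whose
    attended sessions always count).
    """
    if not record["attended"]:
        return False
    decision = record.get("decision")
    return decision in (None, "", "NA", FULL)
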