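"""Experiment designs: trial schedules, target geometry, and error-drive sequences.

Encodes the eight group designs of four center-out reaching experiments that
manipulate target jumps, target size, and error-clamped cursor feedback to
dissociate sensory prediction errors (SPEs, a mismatch between expected and
displayed cursor direction) from task performance errors (TPEs, the cursor
missing the target).

Angle convention: counterclockwise positive, measured from the start-to-
original-target line.  Every group's perturbation is sign-normalized on
construction so that compensation is a positive hand deviation (the 30-degree
clockwise jump group of Experiment 4 is flipped on load).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Block",
    "Feedback",
    "TargetLayout",
    "Trial",
    "Schedule",
    "DriveSeries",
    "CYCLE_LEN",
    "DEFAULT_TARGET_SEED",
    "DESIGNS",
    "build_schedule",
    "target_direction_sequence",
    "cursor_outcome",
    "drive_sequence",
    "schedule_to_frame",
]

#: Trials per cycle used throughout (cycle-averaged analyses).
CYCLE_LEN = 10

#: The pseudo-random target order was fixed across all participants of the
#: study; this package realizes that as a fixed default seed.
DEFAULT_TARGET_SEED = 1915


class Block(str, Enum):
    BASELINE_NOFB = "baseline_nofb"
    BASELINE_FB = "baseline_fb"
    LEARNING = "learning"
    WASHOUT_NOFB = "washout_nofb"
    WASHOUT_FB = "washout_fb"


class Feedback(str, Enum):
    NONE = "none"
    VERIDICAL = "veridical"
    CLAMPED = "clamped"


@dataclass(frozen=True)
class TargetLayout:
    """Radial target arrangement: 4 targets, 90 degrees apart, 10 cm out."""

    directions: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    reach_distance: float = 10.0  # cm
    start_diameter: float = 0.9  # cm
    target_diameter: float = 0.98  # cm

    def __post_init__(self) -> None:
        if len(set(self.directions)) != len(self.directions):
            raise ValueError("target directions must be distinct")
        if self.reach_distance <= 0:
            raise ValueError("reach_distance must be positive")
        if self.start_diameter <= 0 or self.target_diameter <= 0:
            raise ValueError("diameters must be positive")


@dataclass(frozen=True)
class Trial:
    """One trial of a schedule.

    ``jump_deg`` is the mid-reach angular displacement of the target
    (CCW positive, 0 = no jump); ``clamp_offset_deg`` is the fixed cursor
    direction relative to the original target and is meaningful only when
    ``feedback`` is clamped.
    """

    index: int  # 1-based
    block: Block
    target_direction: float
    jump_deg: float = 0.0
    jumped_target_diameter: float = 0.98
    feedback: Feedback = Feedback.VERIDICAL
    clamp_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.jump_deg != 0.0 and self.block is not Block.LEARNING:
            raise ValueError("target jumps occur only in the learning block")
        if self.feedback is Feedback.CLAMPED and self.block is not Block.LEARNING:
            raise ValueError("clamped feedback occurs only in the learning block")
        if self.feedback is not Feedback.CLAMPED and self.clamp_offset_deg != 0.0:
            raise ValueError("clamp_offset_deg requires clamped feedback")


@dataclass(frozen=True)
class Schedule:
    experiment: str
    group: str
    trials: tuple[Trial, ...]
    layout: TargetLayout
    n_subjects_nominal: int
    #: Maximum relevant error angle of the design; used as the upper bound on
    #: lumped error drives when fitting (10 deg in Experiment 1).
    max_error_deg: float = 10.0
    sign_flipped: bool = False  # True where a CW perturbation was normalized

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_cycles(self) -> int:
        return len(self.trials) // CYCLE_LEN

    def blocks(self) -> list[Block]:
        return [t.block for t in self.trials]

    def block_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.block.value] = counts.get(t.block.value, 0) + 1
        return counts


@dataclass
class DriveSeries:
    """Per-cycle error-drive indicators feeding the state-space models.

    ``spe_on``/``tpe_on`` flag cycles on which the respective error is
    present (learning cycles only); ``fit_mask`` flags cycles that enter
    model fits (feedback-washout cycles are excluded because the clamp is
    removed there and the SPE is no longer constant).
    """

    cycle_index: np.ndarray  # 1-based
    spe_on: np.ndarray
    tpe_on: np.ndarray
    fit_mask: np.ndarray
    block: list[Block] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycle_index)


# ---------------------------------------------------------------------------
# design table
# ---------------------------------------------------------------------------

# (block, n_trials) sequences
_BLOCKS_E12 = (
    (Block.BASELINE_NOFB, 20),
    (Block.BASELINE_FB, 20),
    (Block.LEARNING, 240),
    (Block.WASHOUT_NOFB, 20),
    (Block.WASHOUT_FB, 20),
)
_BLOCKS_E3 = (
    (Block.BASELINE_FB, 40),
    (Block.LEARNING, 200),
    (Block.WASHOUT_NOFB, 40),
    (Block.WASHOUT_FB, 120),
)
# Experiment 4 group 1 washes out with feedback first, then without.
_BLOCKS_E4G1 = (
    (Block.BASELINE_NOFB, 20),
    (Block.BASELINE_FB, 20),
    (Block.LEARNING, 240),
    (Block.WASHOUT_FB, 20),
    (Block.WASHOUT_NOFB, 20),
)


@dataclass(frozen=True)
class _Design:
    blocks: tuple[tuple[Block, int], ...]
    jump_deg: float
    clamp_offset_deg: float | None  # None = veridical feedback during learning
    start_diameter: float
    target_diameter: float
    jumped_target_diameter: float
    n_subjects: int
    max_error_deg: float
    sign_flipped: bool = False


DESIGNS: dict[tuple[str, str], _Design] = {
    # Experiment 1: 10 deg CCW jump, cursor clamped at the original target.
    # Miss keeps the original 0.98 cm target (cursor misses -> TPE); Hit
    # enlarges the jumped target to 4.6 cm (cursor hits -> no TPE).
    ("E1", "Miss"): _Design(_BLOCKS_E12, 10.0, 0.0, 0.9, 0.98, 0.98, 15, 10.0),
    ("E1", "Hit"): _Design(_BLOCKS_E12, 10.0, 0.0, 0.9, 0.98, 4.6, 15, 10.0),
    # Experiment 2: as E1 Miss but subjects instructed to ignore the jump;
    # 10 or 20 deg amplitude, cursor clamped at the original target.
    ("E2", "J10"): _Design(_BLOCKS_E12, 10.0, 0.0, 0.9, 0.98, 0.98, 15, 10.0),
    ("E2", "J20"): _Design(_BLOCKS_E12, 20.0, 0.0, 0.9, 0.98, 0.98, 15, 20.0),
    # Experiment 3: 30 deg CCW error clamp; Clamp keeps the target in place
    # (cursor misses -> TPE), ClampJump jumps it 30 deg so the clamped cursor
    # lands on it (no TPE).
    ("E3", "Clamp"): _Design(_BLOCKS_E3, 0.0, 30.0, 1.2, 1.5, 1.5, 15, 30.0),
    ("E3", "ClampJump"): _Design(_BLOCKS_E3, 30.0, 30.0, 1.2, 1.5, 1.5, 15, 30.0),
    # Experiment 4: veridical cursor (no SPE); target jumps create TPEs.
    ("E4", "J10CCW"): _Design(_BLOCKS_E4G1, 10.0, None, 0.9, 0.98, 0.98, 10, 10.0),
    ("E4", "J30CW"): _Design(
        _BLOCKS_E3, 30.0, None, 1.2, 1.5, 1.5, 15, 30.0, sign_flipped=True
    ),
}

_GROUP_ALIASES = {"E4_J10CCW": "J10CCW", "E4_J30CW": "J30CW", "Clamp+Jump": "ClampJump"}


def target_direction_sequence(
    n_trials: int, seed: int = DEFAULT_TARGET_SEED
) -> np.ndarray:
    """Pseudo-random target order: each direction once per 4-trial window.

    Deterministic given ``seed``; the study used a single fixed order for all
    participants, realized here by :data:`DEFAULT_TARGET_SEED`.
    """
    if n_trials % 4 != 0:
        raise ValueError(f"n_trials must be divisible by 4, got {n_trials}")
    rng = np.random.default_rng(seed)
    dirs = np.array([0.0, 90.0, 180.0, 270.0])
    out = np.empty(n_trials)
    for i in range(n_trials // 4):
        out[4 * i : 4 * i + 4] = rng.permutation(dirs)
    return out


def cursor_outcome(
    jump_deg: float,
    clamp_offset_deg: float,
    target_diameter: float,
    reach_distance: float = 10.0,
    cursor_radius: float = 0.0,
) -> str:
    """Geometric hit/miss determination for clamped cursor feedback.

    The cursor endpoint lies ``reach_distance`` along ``clamp_offset_deg``;
    the (possibly jumped) target centre lies ``reach_distance`` along
    ``jump_deg``.  Their separation is the chord 2 R sin(|jump - clamp| / 2);
    a hit requires it not to exceed the target radius (plus an optional
    cursor radius; the cursor is a point by default).
    """
    if target_diameter <= 0 or reach_distance <= 0:
        raise ValueError("target_diameter and reach_distance must be positive")
    sep = abs(jump_deg - clamp_offset_deg)
    chord = 2.0 * reach_distance * math.sin(math.radians(sep) / 2.0)
    return "hit" if chord <= target_diameter / 2.0 + cursor_radius else "miss"


def build_schedule(experiment: str, group: str) -> Schedule:
    """Construct the trial schedule for one of the eight group designs."""
    group = _GROUP_ALIASES.get(group, group)
    key = (experiment, group)
    if key not in DESIGNS:
        known = ", ".join(f"{e}/{g}" for e, g in sorted(DESIGNS))
        raise ValueError(f"unknown design {experiment}/{group}; known: {known}")
    d = DESIGNS[key]
    n_total = sum(n for _, n in d.blocks)
    dirs = target_direction_sequence(n_total)
    layout = TargetLayout(
        start_diameter=d.start_diameter, target_diameter=d.target_diameter
    )

    trials: list[Trial] = []
    i = 0
    for block, n in d.blocks:
        for _ in range(n):
            if block is Block.LEARNING:
                fb = Feedback.VERIDICAL if d.clamp_offset_deg is None else Feedback.CLAMPED
                trials.append(
                    Trial(
                        index=i + 1,
                        block=block,
                        target_direction=dirs[i],
                        jump_deg=d.jump_deg,
                        jumped_target_diameter=d.jumped_target_diameter,
                        feedback=fb,
                        clamp_offset_deg=d.clamp_offset_deg or 0.0,
                    )
                )
            else:
                fb = (
                    Feedback.NONE
                    if block in (Block.BASELINE_NOFB, Block.WASHOUT_NOFB)
                    else Feedback.VERIDICAL
                )
                trials.append(
                    Trial(
                        index=i + 1,
                        block=block,
                        target_direction=dirs[i],
                        jumped_target_diameter=d.target_diameter,
                        feedback=fb,
                    )
                )
            i += 1
    return Schedule(
        experiment=experiment,
        group=group,
        trials=tuple(trials),
        layout=layout,
        n_subjects_nominal=d.n_subjects,
        max_error_deg=d.max_error_deg,
        sign_flipped=d.sign_flipped,
    )


def drive_sequence(schedule: Schedule) -> DriveSeries:
    """Per-cycle SPE/TPE indicators and the fit mask for a schedule.

    SPE presence is a property of the design: clamped-cursor experiments
    (E1, E3) induce an SPE on learning cycles; E2 (hand and clamp aligned at
    the original target) and E4 (veridical cursor) do not.  TPE presence on
    learning cycles follows the hit/miss geometry: for clamped feedback the
    cursor travels along the clamp, for veridical feedback it initially
    travels toward the original target, and the test is against the jumped
    target.  Both drives are off on baseline and washout cycles (no constant
    error, or no cursor at all); the fit mask excludes feedback-washout
    cycles.
    """
    n_cycles = schedule.n_trials // CYCLE_LEN
    if n_cycles * CYCLE_LEN != schedule.n_trials:
        raise ValueError("trial count is not a whole number of cycles")
    spe = np.zeros(n_cycles, dtype=int)
    tpe = np.zeros(n_cycles, dtype=int)
    mask = np.ones(n_cycles, dtype=bool)
    blocks: list[Block] = []
    spe_present = schedule.experiment in ("E1", "E3")
    for c in range(n_cycles):
        window = schedule.trials[c * CYCLE_LEN : (c + 1) * CYCLE_LEN]
        blk = {t.block for t in window}
        if len(blk) != 1:
            raise ValueError("block boundaries must fall on cycle boundaries")
        block = window[0].block
        blocks.append(block)
        if block is Block.LEARNING:
            t0 = window[0]
            spe[c] = int(spe_present)
            cursor_dir = t0.clamp_offset_deg if t0.feedback is Feedback.CLAMPED else 0.0
            outcome = cursor_outcome(
                t0.jump_deg,
                cursor_dir,
                t0.jumped_target_diameter,
                schedule.layout.reach_distance,
            )
            tpe[c] = int(outcome == "miss")
        if block is Block.WASHOUT_FB:
            mask[c] = False
    return DriveSeries(
        cycle_index=np.arange(1, n_cycles + 1),
        spe_on=spe,
        tpe_on=tpe,
        fit_mask=mask,
        block=blocks,
    )


def schedule_to_frame(schedule: Schedule, subject: int = 1) -> pd.DataFrame:
    """Tidy one-row-per-trial table of a schedule."""
    rows = []
    for t in schedule.trials:
        rows.append(
            {
                "subject": subject,
                "experiment": schedule.experiment,
                "group": schedule.group,
                "trial": t.index,
                "cycle": (t.index - 1) // CYCLE_LEN + 1,
                "block": t.block.value,
                "target_dir_deg": t.target_direction,
                "jump_deg": t.jump_deg,
                "clamp_offset_deg": t.clamp_offset_deg,
                "target_diameter_cm": t.jumped_target_diameter,
                "feedback": t.feedback.value,
            }
        )
    return pd.DataFrame(rows)
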