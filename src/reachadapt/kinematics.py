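"""Reach-trajectory preprocessing: from raw hand paths to cycle series.

Pipeline, per trial: zero-phase low-pass filtering of the hand path (10-Hz
Butterworth), speed by differentiation, movement onset at the first crossing
of 5% of peak speed (RT relative to the go cue), and the primary dependent
variable — the signed angle between the start-to-original-target line and the
start-to-hand line at peak movement velocity (hand deviation, CCW positive).
Bad trials (no movement, stylus lift, |deviation| > 85 deg) are excluded;
per-subject baseline bias (mean deviation over all valid baseline trials) is
subtracted; trials are averaged in 10-trial cycles and phase summaries
(early/late learning, after-effects, RT change) are taken over the defining
10-trial windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .design import CYCLE_LEN, Block, Schedule

__all__ = [
    "RawTrial",
    "TrialMetrics",
    "CycleSeries",
    "PhaseMetrics",
    "lowpass_filter",
    "movement_onset_rt",
    "hand_deviation_at_peak",
    "process_trial",
    "apply_exclusions",
    "baseline_correct",
    "cycle_average",
    "phase_metrics",
    "preprocess_subject",
    "TRIAL_TABLE_COLUMNS",
]

#: Peak speed below this (cm/s) marks a trial as "no movement".
NO_MOVEMENT_FLOOR = 2.0
#: Hand deviations strictly above this magnitude (deg) are excluded.
DEVIATION_LIMIT = 85.0

TRIAL_TABLE_COLUMNS = [
    "subject", "experiment", "group", "trial", "cycle", "block",
    "hand_dev_deg", "hand_dev_bc_deg", "rt_ms", "excluded", "reason",
]


@dataclass
class RawTrial:
    """Uniformly sampled hand path for one trial (positions in cm relative to
    the start centre; times in seconds; go cue defines RT zero)."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    go_cue_time: float = 0.0
    stylus_lift: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class TrialMetrics:
    hand_deviation: float  # deg, CCW positive, relative to the original target
    rt: float  # ms
    peak_speed: float  # cm/s
    excluded: bool = False
    exclusion_reason: str = "none"


@dataclass
class CycleSeries:
    """Per-cycle means (valid trials only) for one subject or a group mean."""

    subject: int | str
    cycle_index: np.ndarray
    mean_deviation: np.ndarray  # baseline-corrected, deg
    mean_rt: np.ndarray  # ms
    n_valid: np.ndarray

    def __len__(self) -> int:
        return len(self.cycle_index)


@dataclass
class PhaseMetrics:
    early_learning: float
    late_learning: float
    early_nofb_washout: float
    early_fb_washout: float
    late_washout: float
    rt_change_early: float


def lowpass_filter(raw: RawTrial, cutoff_hz: float = 10.0, order: int = 4) -> RawTrial:
    """Zero-phase Butterworth low-pass on x and y (forward-backward)."""
    if len(raw.time) < 8:
        raise ValueError("need at least 8 samples to filter")
    fs = 1.0 / raw.dt
    if cutoff_hz >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {fs / 2} Hz")
    b, a = butter(order, cutoff_hz, fs=fs)
    return RawTrial(
        time=raw.time,
        x=filtfilt(b, a, raw.x),
        y=filtfilt(b, a, raw.y),
        go_cue_time=raw.go_cue_time,
        stylus_lift=raw.stylus_lift,
        meta=dict(raw.meta),
    )


def _speed(raw: RawTrial) -> np.ndarray:
    # central differences; one-sided at the endpoints
    vx = np.gradient(raw.x, raw.time)
    vy = np.gradient(raw.y, raw.time)
    return np.hypot(vx, vy)


def movement_onset_rt(raw: RawTrial) -> dict:
    """Movement onset at the first crossing of 5% of peak speed.

    Returns onset time (s), RT (ms, relative to the go cue) and peak speed;
    ``no_movement`` is flagged when the peak speed stays below the floor.
    """
    speed = _speed(raw)
    peak = float(np.max(speed))
    if peak < NO_MOVEMENT_FLOOR:
        return {"onset_time": np.nan, "rt": np.nan, "peak_speed": peak,
                "no_movement": True}
    onset_idx = int(np.argmax(speed >= 0.05 * peak))
    onset_time = float(raw.time[onset_idx])
    return {
        "onset_time": onset_time,
        "rt": (onset_time - raw.go_cue_time) * 1000.0,
        "peak_speed": peak,
        "no_movement": False,
    }


def hand_deviation_at_peak(
    raw: RawTrial, original_target_dir: float, reach_distance: float = 10.0
) -> float:
    """Signed CCW angle (deg) between the start-to-target line and the
    start-to-hand line at peak movement velocity, wrapped to (-180, 180].

    The peak-velocity search runs from movement onset to the first crossing
    of the reach distance (where the cursor froze), falling back to the whole
    trial when that radius is never reached.
    """
    onset = movement_onset_rt(raw)
    if onset["no_movement"]:
        raise ValueError("no movement detected; deviation undefined")
    speed = _speed(raw)
    radius = np.hypot(raw.x, raw.y)
    i0 = int(np.argmax(raw.time >= onset["onset_time"]))
    crossed = np.nonzero(radius >= reach_distance)[0]
    i1 = int(crossed[0]) + 1 if len(crossed) else len(speed)
    if i1 <= i0:
        i0, i1 = 0, len(speed)
    ipk = i0 + int(np.argmax(speed[i0:i1]))
    hx, hy = raw.x[ipk], raw.y[ipk]
    if np.hypot(hx, hy) == 0.0:
        raise ValueError("hand at start position at peak velocity")
    hand_ang = np.degrees(np.arctan2(hy, hx))
    dev = hand_ang - original_target_dir
    return float((dev + 180.0) % 360.0 - 180.0)


def process_trial(
    raw: RawTrial,
    original_target_dir: float,
    reach_distance: float = 10.0,
    cutoff_hz: float = 10.0,
) -> TrialMetrics:
    """Filter one trial and extract deviation, RT and peak speed."""
    if raw.stylus_lift:
        return TrialMetrics(np.nan, np.nan, np.nan, True, "stylus_lift")
    filt = lowpass_filter(raw, cutoff_hz)
    onset = movement_onset_rt(filt)
    if onset["no_movement"]:
        return TrialMetrics(np.nan, np.nan, onset["peak_speed"], True, "no_movement")
    try:
        dev = hand_deviation_at_peak(filt, original_target_dir, reach_distance)
    except ValueError:
        return TrialMetrics(np.nan, onset["rt"], onset["peak_speed"], True, "no_movement")
    return TrialMetrics(dev, onset["rt"], onset["peak_speed"])


def apply_exclusions(metrics: list[TrialMetrics]) -> tuple[list[TrialMetrics], float]:
    """Flag bad trials (in place) and report the excluded fraction.

    Adds the large-deviation rule: |deviation| strictly greater than 85 deg.
    """
    for m in metrics:
        if not m.excluded and abs(m.hand_deviation) > DEVIATION_LIMIT:
            m.excluded = True
            m.exclusion_reason = "deviation_gt_85"
    frac = sum(m.excluded for m in metrics) / max(len(metrics), 1)
    return metrics, frac


def baseline_correct(
    deviations: np.ndarray, schedule: Schedule, valid: np.ndarray | None = None
) -> np.ndarray:
    """Subtract the mean deviation over all valid baseline trials."""
    deviations = np.asarray(deviations, float)
    blocks = schedule.blocks()
    is_base = np.array(
        [b in (Block.BASELINE_NOFB, Block.BASELINE_FB) for b in blocks]
    )
    if valid is None:
        valid = np.isfinite(deviations)
    use = is_base & np.asarray(valid, bool) & np.isfinite(deviations)
    if not use.any():
        raise ValueError("no valid baseline trials; cannot estimate bias")
    return deviations - float(deviations[use].mean())


def cycle_average(
    values: np.ndarray,
    valid: np.ndarray | None = None,
    cycle_len: int = CYCLE_LEN,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean over valid trials in consecutive ``cycle_len`` windows.

    Cycles with zero valid trials yield NaN.  Returns (means, n_valid).
    """
    values = np.asarray(values, float)
    if len(values) % cycle_len != 0:
        raise ValueError(f"trial count {len(values)} not divisible by {cycle_len}")
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, bool) & np.isfinite(values)
    n_cycles = len(values) // cycle_len
    v = np.where(valid, values, 0.0).reshape(n_cycles, cycle_len)
    n = valid.reshape(n_cycles, cycle_len).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, v.sum(axis=1) / np.maximum(n, 1), np.nan)
    return means, n


def _block_window(blocks, which: Block, first: bool, k: int = 10) -> np.ndarray:
    idx = np.nonzero(np.array([b is which for b in blocks]))[0]
    if len(idx) == 0:
        raise ValueError(f"block {which.value} missing from schedule")
    return idx[:k] if first else idx[-k:]


def phase_metrics(
    deviations_bc: np.ndarray,
    rt_ms: np.ndarray,
    schedule: Schedule,
    valid: np.ndarray | None = None,
) -> PhaseMetrics:
    """Phase summaries over the defining 10-trial windows.

    Early/late learning = first/last 10 learning trials; early after-effect =
    first 10 no-feedback washout trials; sustained after-effect = first 10
    feedback washout trials; late washout = last 10 washout trials of the
    final washout block.  RT change = mean RT of the first 10 learning trials
    minus mean RT of the last 10 baseline trials.
    """
    deviations_bc = np.asarray(deviations_bc, float)
    rt_ms = np.asarray(rt_ms, float)
    blocks = schedule.blocks()
    if valid is None:
        valid = np.isfinite(deviations_bc)
    valid = np.asarray(valid, bool)

    def mean_over(idx, series):
        use = idx[valid[idx] & np.isfinite(series[idx])]
        return float(series[use].mean()) if len(use) else float("nan")

    learn_first = _block_window(blocks, Block.LEARNING, True)
    learn_last = _block_window(blocks, Block.LEARNING, False)
    nofb_first = _block_window(blocks, Block.WASHOUT_NOFB, True)
    fb_first = _block_window(blocks, Block.WASHOUT_FB, True)
    # last washout block in schedule order
    wash_idx = np.nonzero(
        np.array([b in (Block.WASHOUT_NOFB, Block.WASHOUT_FB) for b in blocks])
    )[0]
    base_fb_last = _block_window(blocks, Block.BASELINE_FB, False)
    return PhaseMetrics(
        early_learning=mean_over(learn_first, deviations_bc),
        late_learning=mean_over(learn_last, deviations_bc),
        early_nofb_washout=mean_over(nofb_first, deviations_bc),
        early_fb_washout=mean_over(fb_first, deviations_bc),
        late_washout=mean_over(wash_idx[-10:], deviations_bc),
        rt_change_early=mean_over(learn_first, rt_ms) - mean_over(base_fb_last, rt_ms),
    )


def preprocess_subject(
    raws: list[RawTrial],
    schedule: Schedule,
    subject: int = 1,
    cutoff_hz: float = 10.0,
) -> tuple[pd.DataFrame, CycleSeries]:
    """Run the full pipeline on one subject's raw trials.

    Returns the tidy trial table (columns :data:`TRIAL_TABLE_COLUMNS`) and
    the baseline-corrected cycle series.  Deviations are sign-normalized for
    designs whose perturbation was clockwise.
    """
    if len(raws) != schedule.n_trials:
        raise ValueError(
            f"{len(raws)} raw trials for a {schedule.n_trials}-trial schedule"
        )
    metrics = [
        process_trial(raw, trial.target_direction, schedule.layout.reach_distance,
                      cutoff_hz)
        for raw, trial in zip(raws, schedule.trials)
    ]
    metrics, _ = apply_exclusions(metrics)
    dev = np.array([m.hand_deviation for m in metrics])
    if schedule.sign_flipped:
        dev = -dev
    rt = np.array([m.rt for m in metrics])
    valid = np.array([not m.excluded for m in metrics])
    dev_bc = baseline_correct(dev, schedule, valid)
    cyc_dev, n_valid = cycle_average(np.where(valid, dev_bc, np.nan))
    cyc_rt, _ = cycle_average(np.where(valid, rt, np.nan))
    table = pd.DataFrame(
        {
            "subject": subject,
            "experiment": schedule.experiment,
            "group": schedule.group,
            "trial": [t.index for t in schedule.trials],
            "cycle": [(t.index - 1) // CYCLE_LEN + 1 for t in schedule.trials],
            "block": [t.block.value for t in schedule.trials],
            "hand_dev_deg": dev,
            "hand_dev_bc_deg": np.where(valid, dev_bc, np.nan),
            "rt_ms": rt,
            "excluded": [m.excluded for m in metrics],
            "reason": [m.exclusion_reason for m in metrics],
        }
    )[TRIAL_TABLE_COLUMNS]
    series = CycleSeries(
        subject=subject,
        cycle_index=np.arange(1, len(cyc_dev) + 1),
        mean_deviation=cyc_dev,
        mean_rt=cyc_rt,
        n_valid=n_valid,
    )
    return table, series
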