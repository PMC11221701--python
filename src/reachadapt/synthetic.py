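"""Synthetic cohorts with the statistical structure the analysis assumes.

Two resolutions:

* cycle level — model-generated learning traces plus independent Gaussian
  cycle noise per subject, for fitting and bootstrap tests that need not run
  the kinematic layer;
* raw-trajectory level — per-trial straight-line reaches with a minimum-jerk
  speed profile, angular motor noise, and programmed reaction times (with a
  strategy RT cost on re-aiming trials), for exercising the preprocessing
  pipeline end to end.

Ground truth (intended aim per trial, programmed RT, generating parameters,
noiseless model trace) is stored alongside the data for recovery tests.

The deviation a subject produces is modeled as strategic aim (re-aiming at a
jumped target, engaged a couple of trials after the first jump) plus the
implicit learned state of that trial's cycle; under ``aim_original`` or
``ignore_jump`` the strategic term is zero and the model state carries the
whole deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CYCLE_LEN, Block, DriveSeries, Schedule, drive_sequence
from .models import (
    ModelParams,
    StateTrace,
    simulate_independent,
    simulate_interaction,
    simulate_spe,
)
from .kinematics import RawTrial

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "aim_sequence",
    "model_cycle_trace",
    "generate_cycle_traces",
    "generate_raw_trials",
    "minimum_jerk_displacement",
    "ONSET_TAU",
]

# Fraction of movement time at which a minimum-jerk speed profile first
# crosses 5% of its peak: solves 30 t^2 (1-t)^2 = 0.05 * 1.875, i.e.
# t(1-t) = sqrt(0.05)/4.  Used to place movement start so the programmed RT
# is the 5%-of-peak onset the pipeline measures.
ONSET_TAU = (1.0 - np.sqrt(1.0 - np.sqrt(0.05))) / 2.0


@dataclass
class GeneratorConfig:
    """Study-condition defaults for cohort generation.

    Trial-level angular noise 3 deg and cycle-level noise 1.5 deg emulate the
    spread of cycle-mean group data; RTs are ~400 ms baseline with a ~100 ms
    cost on strategic re-aiming trials plus additive lognormal jitter.
    """

    generating_model: str = "spe_only"  # spe_only | independent | interaction | strategy_plus_spe
    params: ModelParams = field(default_factory=lambda: ModelParams(a_spe=0.9, b_spe=1.0))
    aim_policy: str = "aim_original"  # aim_original | aim_jumped | ignore_jump
    angular_noise_sd: float = 3.0  # deg, per trial
    cycle_noise_sd: float = 1.5  # deg, per cycle (cycle-level generator only)
    rt_base: float = 400.0  # ms
    rt_strategy_boost: float = 100.0  # ms, on re-aiming trials
    rt_jitter_median: float = 20.0  # ms, additive lognormal jitter median
    rt_jitter_sigma: float = 0.6  # lognormal sigma (0 disables jitter spread)
    sampling_rate: float = 100.0  # Hz
    n_subjects: int = 15
    seed: int = 0
    strategy_lag_trials: int = 2  # learning trials before the aim switch
    movement_time: float = 0.6  # s
    movement_extent: float = 14.0  # cm, > reach distance so 10 cm is crossed

    def __post_init__(self) -> None:
        if self.angular_noise_sd < 0 or self.cycle_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_rate <= 20:
            raise ValueError("sampling_rate must exceed 20 Hz")


@dataclass
class SyntheticCohort:
    schedule: Schedule
    config: GeneratorConfig
    subjects: list[list[RawTrial]]
    truth: pd.DataFrame  # subject, trial, aim_deg, rt_ms, strategy
    params: ModelParams
    state: StateTrace


def _simulate(model: str, params: ModelParams, drive: DriveSeries) -> StateTrace:
    if model in ("spe_only", "strategy_plus_spe"):
        return simulate_spe(params, drive)
    if model == "independent":
        return simulate_independent(params, drive)
    if model == "interaction":
        return simulate_interaction(params, drive)
    raise ValueError(f"unknown generating model {model!r}")


def aim_sequence(
    schedule: Schedule,
    policy: str,
    learned_state: StateTrace | None = None,
    lag: int = 2,
) -> np.ndarray:
    """Per-trial intended movement direction (absolute degrees).

    Strategic aim is the original target under ``aim_original`` /
    ``ignore_jump`` and the jumped target under ``aim_jumped`` (engaged
    ``lag`` learning trials after the first jump); the implicit state of the
    trial's cycle adds on top.
    """
    if policy not in ("aim_original", "aim_jumped", "ignore_jump"):
        raise ValueError(f"unknown aim policy {policy!r}")
    aims = np.empty(schedule.n_trials)
    learn_count = 0
    for i, trial in enumerate(schedule.trials):
        aim = trial.target_direction
        if trial.block is Block.LEARNING:
            if policy == "aim_jumped" and learn_count >= lag:
                aim += trial.jump_deg
            learn_count += 1
        if learned_state is not None:
            aim += learned_state.x_net[i // CYCLE_LEN]
        aims[i] = aim
    return aims


def model_cycle_trace(
    model: str,
    params: ModelParams,
    drive: DriveSeries,
    strategy_jump_deg: float = 0.0,
    lag: int = 2,
) -> np.ndarray:
    """Noiseless cycle-level deviation trace for a generating model.

    For ``strategy_plus_spe`` the strategic re-aim contributes the jump
    magnitude on learning cycles (pro-rated on the first cycle for the
    ``lag`` pre-switch trials) on top of the implicit SPE trace.
    """
    trace = _simulate(model, params, drive).x_net.copy()
    if model == "strategy_plus_spe" and strategy_jump_deg != 0.0:
        learning = np.array([b is Block.LEARNING for b in drive.block])
        strategic = np.where(learning, strategy_jump_deg, 0.0)
        first = np.argmax(learning) if learning.any() else None
        if first is not None and learning.any():
            strategic[first] *= (CYCLE_LEN - lag) / CYCLE_LEN
        trace += strategic
    return trace


def generate_cycle_traces(
    model: str,
    params: ModelParams,
    drive: DriveSeries,
    cycle_noise_sd: float,
    n_subjects: int,
    seed: int,
    strategy_jump_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cohort of per-subject cycle series: model trace + Gaussian cycle noise.

    Returns ``(traces, truth)`` where ``traces`` is (n_subjects, n_cycles)
    and ``truth`` the noiseless trace.  Deterministic given ``seed``.
    """
    truth = model_cycle_trace(model, params, drive, strategy_jump_deg)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, cycle_noise_sd, size=(n_subjects, len(truth)))
    return truth[None, :] + noise, truth


def minimum_jerk_displacement(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _make_trajectory(
    aim_deg: float,
    rt_ms: float,
    config: GeneratorConfig,
    meta: dict,
) -> RawTrial:
    """Straight reach along ``aim_deg`` with a minimum-jerk speed profile.

    Movement start is placed so the 5%-of-peak-speed crossing — the onset
    definition the pipeline applies — falls at the programmed RT.
    """
    dt = 1.0 / config.sampling_rate
    T = config.movement_time
    move_start = rt_ms / 1000.0 - ONSET_TAU * T
    t_end = move_start + T + 0.15
    t = np.arange(0.0, t_end, dt)
    tau = (t - move_start) / T
    s = config.movement_extent * minimum_jerk_displacement(tau)
    th = np.radians(aim_deg)
    return RawTrial(
        time=t, x=s * np.cos(th), y=s * np.sin(th), go_cue_time=0.0, meta=meta
    )


def generate_raw_trials(
    schedule: Schedule, config: GeneratorConfig
) -> SyntheticCohort:
    """Generate a cohort of raw reach trajectories for a schedule."""
    drive = drive_sequence(schedule)
    policy = (
        "aim_jumped"
        if config.generating_model == "strategy_plus_spe"
        else config.aim_policy
    )
    state = _simulate(config.generating_model, config.params, drive)
    base_aims = aim_sequence(schedule, policy, state, config.strategy_lag_trials)

    strategy_flags = np.zeros(schedule.n_trials, dtype=bool)
    learn_count = 0
    for i, trial in enumerate(schedule.trials):
        if trial.block is Block.LEARNING:
            if policy == "aim_jumped" and learn_count >= config.strategy_lag_trials:
                strategy_flags[i] = True
            learn_count += 1

    root = np.random.SeedSequence(config.seed)
    subjects: list[list[RawTrial]] = []
    rows = []
    for s_id, child in enumerate(root.spawn(config.n_subjects), start=1):
        rng = np.random.default_rng(child)
        ang_noise = rng.normal(0.0, config.angular_noise_sd, schedule.n_trials)
        jitter = config.rt_jitter_median * rng.lognormal(
            0.0, config.rt_jitter_sigma, schedule.n_trials
        )
        trials = []
        for i, trial in enumerate(schedule.trials):
            # aims are built perturbation-sign-normalized; emit the physical
            # (mirrored) trajectory for clockwise designs so the pipeline's
            # sign normalization restores positive compensation
            offset = base_aims[i] - trial.target_direction + ang_noise[i]
            if schedule.sign_flipped:
                offset = -offset
            aim = trial.target_direction + offset
            rt = (
                config.rt_base
                + (config.rt_strategy_boost if strategy_flags[i] else 0.0)
                + jitter[i]
            )
            meta = {"subject": s_id, "trial": trial.index}
            trials.append(_make_trajectory(aim, rt, config, meta))
            rows.append(
                {
                    "subject": s_id,
                    "trial": trial.index,
                    "aim_deg": aim,
                    "dev_norm_deg": base_aims[i] - trial.target_direction + ang_noise[i],
                    "rt_ms": rt,
                    "strategy": bool(strategy_flags[i]),
                }
            )
        subjects.append(trials)
    return SyntheticCohort(
        schedule=schedule,
        config=config,
        subjects=subjects,
        truth=pd.DataFrame(rows),
        params=config.params,
        state=state,
    )
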