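"""Forward dynamics of the trial-by-trial state-space learning models.

Three variants of the classic linear state-space model of motor adaptation,
x(n+1) = A x(n) + B e(n), at one update per 10-trial cycle:

* SPE-only: a single process driven by the sensory prediction error.
* Independent Error: two processes (SPE-driven and TPE-driven) whose states
  add; task errors recruit their own implicit learner.
* Interaction: a single SPE-driven process whose retention and drive are
  multiplied by gains G_A, G_B on cycles without a TPE (both gains are fixed
  at 1 when a TPE is present).

Because the clamp holds the error constant during learning, the products
B_SPE*SPE and B_TPE*TPE are lumped single parameters in degrees/cycle; the
drive indicator sequences switch them on and off.  Returned traces hold the
post-update state for each cycle (the state after experiencing that cycle's
error), starting from x0 = 0 by default since the data are baseline-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .design import DriveSeries

__all__ = ["ModelParams", "StateTrace", "simulate_spe", "simulate_independent",
           "simulate_interaction", "asymptote", "expand_drive_to_trials"]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the learning models; unused fields may stay ``None``.

    ``b_spe`` and ``b_tpe`` are the lumped drives B_SPE*SPE and B_TPE*TPE in
    degrees/cycle.  Retention factors live in [0, 1]; lumped drives in
    [0, drive_bound]; gains are non-negative.
    """

    a_spe: float | None = None
    b_spe: float | None = None
    a_tpe: float | None = None
    b_tpe: float | None = None
    g_a: float | None = None
    g_b: float | None = None

    def validate(self, drive_bound: float = np.inf) -> "ModelParams":
        for name in ("a_spe", "a_tpe"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("b_spe", "b_tpe"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= drive_bound:
                raise ValueError(f"{name}={v} outside [0, {drive_bound}]")
        for name in ("g_a", "g_b"):
            v = getattr(self, name)
            if v is not None and v < 0.0:
                raise ValueError(f"{name}={v} must be non-negative")
        return self

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class StateTrace:
    """Per-cycle model states; ``x_net = x_spe + x_tpe`` for the two-process
    model and equals the single state otherwise."""

    x_spe: np.ndarray
    x_tpe: np.ndarray
    x_net: np.ndarray

    def __len__(self) -> int:
        return len(self.x_net)


def _linear_trace(a: float, b: float, u: np.ndarray, x0: float = 0.0) -> np.ndarray:
    """x(n) = a x(n-1) + b u(n), post-update states, x(before first) = x0."""
    if len(u) == 0:
        return np.empty(0)
    y, _ = lfilter([b], [1.0, -a], np.asarray(u, dtype=float), zi=np.array([a * x0]))
    return y


def simulate_spe(
    params: ModelParams, drive: DriveSeries, x0: float = 0.0
) -> StateTrace:
    """Single-process SPE learner: x(n+1) = A_SPE x(n) + B_SPE*SPE spe_on(n)."""
    if params.a_spe is None or params.b_spe is None:
        raise ValueError("a_spe and b_spe are required")
    params.validate()
    if not np.isfinite(x0):
        raise ValueError("x0 must be finite")
    x = _linear_trace(params.a_spe, params.b_spe, drive.spe_on, x0)
    return StateTrace(x_spe=x, x_tpe=np.zeros_like(x), x_net=x)


def simulate_independent(
    params: ModelParams,
    drive: DriveSeries,
    x0_spe: float = 0.0,
    x0_tpe: float = 0.0,
    retention_on_net: bool = False,
) -> StateTrace:
    """Two-process Independent Error model; net state is the processes' sum.

    ``retention_on_net=True`` switches the SPE process to retain the net
    state instead of its own (an alternative printed form of the update);
    the per-process form is the default.
    """
    for name in ("a_spe", "b_spe", "a_tpe", "b_tpe"):
        if getattr(params, name) is None:
            raise ValueError(f"{name} is required for the Independent model")
    params.validate()
    if not retention_on_net:
        x_spe = _linear_trace(params.a_spe, params.b_spe, drive.spe_on, x0_spe)
        x_tpe = _linear_trace(params.a_tpe, params.b_tpe, drive.tpe_on, x0_tpe)
    else:
        n = len(drive)
        x_spe = np.empty(n)
        x_tpe = np.empty(n)
        s, t = x0_spe, x0_tpe
        for i in range(n):
            s_new = params.a_spe * (s + t) + params.b_spe * drive.spe_on[i]
            t = params.a_tpe * t + params.b_tpe * drive.tpe_on[i]
            s = s_new
            x_spe[i], x_tpe[i] = s, t
    return StateTrace(x_spe=x_spe, x_tpe=x_tpe, x_net=x_spe + x_tpe)


def simulate_interaction(
    params: ModelParams, drive: DriveSeries, x0: float = 0.0
) -> StateTrace:
    """Gain-modulated SPE learner: x(n+1) = G_A A_SPE x(n) + G_B B_SPE*SPE(n).

    The gains apply only on cycles where no TPE is present; where
    ``tpe_on = 1`` they are held at 1 (modulation is defined relative to the
    TPE-present condition).
    """
    for name in ("a_spe", "b_spe", "g_a", "g_b"):
        if getattr(params, name) is None:
            raise ValueError(f"{name} is required for the Interaction model")
    params.validate()
    n = len(drive)
    x = np.empty(n)
    state = x0
    for i in range(n):
        ga = 1.0 if drive.tpe_on[i] else params.g_a
        gb = 1.0 if drive.tpe_on[i] else params.g_b
        state = ga * params.a_spe * state + gb * params.b_spe * drive.spe_on[i]
        x[i] = state
    return StateTrace(x_spe=x, x_tpe=np.zeros_like(x), x_net=x)


def asymptote(a: float, b_drive: float) -> float:
    """Fixed point b/(1 - a) of the recursion under constant drive."""
    if not 0.0 <= a < 1.0:
        raise ValueError(f"retention factor a={a} must lie in [0, 1)")
    return b_drive / (1.0 - a)


def expand_drive_to_trials(drive: DriveSeries, trials_per_cycle: int = 10) -> DriveSeries:
    """Repeat each cycle's indicators so the models can be run per trial."""
    rep = lambda v: np.repeat(np.asarray(v), trials_per_cycle)
    n = len(drive) * trials_per_cycle
    return DriveSeries(
        cycle_index=np.arange(1, n + 1),
        spe_on=rep(drive.spe_on),
        tpe_on=rep(drive.tpe_on),
        fit_mask=rep(drive.fit_mask).astype(bool),
        block=[b for b in drive.block for _ in range(trials_per_cycle)],
    )
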