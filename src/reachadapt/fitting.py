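"""Box-constrained least-squares fitting of the learning models.

The models are fit to group-mean cycle series (baseline-corrected hand
deviation per 10-trial cycle) over the masked cycles: baseline, learning and
no-feedback washout.  Feedback-washout cycles are excluded because the clamp
is removed there and the error is no longer constant.

All four fit protocols estimate exactly two free parameters, and every model
trace is affine in its drive/gain parameter (the lumped drive B, or the gain
G_B) for a fixed retention parameter.  The optimizer therefore profiles the
affine parameter out in closed form (a clipped least-squares solution) and
searches the remaining retention/gain axis with a coarse grid, seeded random
probes, and a bounded Brent polish.  This finds the constrained optimum
reliably without depending on a local-solver start.

Sequential protocols, as used for adjudicating the models:

* Independent Error: SPE-only process fit to the no-TPE group; its estimates
  frozen while A_TPE, B_TPE*TPE are fit to the TPE group.
* Interaction: full dynamics fit to one group with gains pinned at 1; those
  estimates frozen while G_A, G_B are fit to the other group, with bootstrap
  CIs (participant resampling) to test whether the gains differ from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .design import DriveSeries
from .models import (
    ModelParams,
    StateTrace,
    _linear_trace,
    simulate_independent,
    simulate_interaction,
    simulate_spe,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "BootstrapCI",
    "FitSpec",
    "fit_spe_only",
    "fit_independent_stage2",
    "fit_interaction",
    "goodness_of_fit",
    "bootstrap_parameter_ci",
    "grid_search_spe_only",
    "fit_by_spec",
]


@dataclass
class FitConfig:
    """Controls for the constrained fits.

    ``drive_bound_deg`` bounds the lumped drives (the design's maximum error
    angle: 10 deg for a 10-deg jump, 30 deg for a 30-deg clamp);
    ``gain_bounds`` bound G_A/G_B (unstated in the source analyses; [0, 3]
    comfortably contains all printed estimates and CIs).  ``n_starts`` random
    probes supplement a ``coarse_grid``-point sweep of the retention axis.
    """

    drive_bound_deg: float = 10.0
    retention_bounds: tuple[float, float] = (0.0, 1.0)
    gain_bounds: tuple[float, float] = (0.0, 3.0)
    n_starts: int = 20
    coarse_grid: int = 41
    tolerance: float = 1e-10
    seed: int = 0
    r2_all_cycles: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class FitResult:
    params: ModelParams
    predicted: StateTrace
    r2: float
    rmse: float
    objective: float
    frozen: tuple[str, ...] = ()
    free: tuple[str, ...] = ()

    def free_values(self) -> dict[str, float]:
        return {name: getattr(self.params, name) for name in self.free}


@dataclass
class BootstrapCI:
    parameter: str
    estimate: float
    lo95: float
    hi95: float
    n_boot: int
    seed: int
    samples: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# profiled 1-D optimizer
# ---------------------------------------------------------------------------

def _profiled_objective(a, y, pq_builder, b_bounds):
    p, q = pq_builder(a)
    denom = float(q @ q)
    if denom <= 0.0:
        b = 0.0
    else:
        b = float(q @ (y - p)) / denom
        b = min(max(b, b_bounds[0]), b_bounds[1])
    r = y - p - b * q
    return float(r @ r), b


def _profiled_fit(y, pq_builder, a_bounds, b_bounds, config: FitConfig):
    """Minimize ||y - p(a) - b q(a)||^2 over box-constrained (a, b)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = a_bounds
    cand = np.concatenate(
        [
            np.linspace(lo, hi, config.coarse_grid),
            rng.uniform(lo, hi, size=config.n_starts),
        ]
    )
    sses = np.array([_profiled_objective(a, y, pq_builder, b_bounds)[0] for a in cand])
    order = np.argsort(cand)
    cand, sses = cand[order], sses[order]
    i = int(np.argmin(sses))
    blo = cand[max(i - 1, 0)]
    bhi = cand[min(i + 1, len(cand) - 1)]
    if bhi > blo:
        res = minimize_scalar(
            lambda a: _profiled_objective(a, y, pq_builder, b_bounds)[0],
            bounds=(blo, bhi),
            method="bounded",
            options={"xatol": max(config.tolerance, 1e-12)},
        )
        a_best = float(res.x) if res.fun <= sses[i] else float(cand[i])
    else:
        a_best = float(cand[i])
    sse, b_best = _profiled_objective(a_best, y, pq_builder, b_bounds)
    return a_best, b_best, sse


def _check_series(observed: np.ndarray, drive: DriveSeries) -> np.ndarray:
    observed = np.asarray(observed, dtype=float)
    if len(observed) != len(drive):
        raise ValueError(
            f"observed series ({len(observed)}) and drive ({len(drive)}) differ"
        )
    mask = np.asarray(drive.fit_mask, dtype=bool)
    if not mask.any():
        raise ValueError("fit mask excludes every cycle")
    if not np.all(np.isfinite(observed[mask])):
        raise ValueError("observed series contains non-finite masked values")
    return mask


def goodness_of_fit(
    observed: np.ndarray, predicted: np.ndarray, mask: np.ndarray | None = None
) -> dict:
    """R^2 (about the observed mean) and RMSE over the (masked) cycles."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if mask is not None:
        observed, predicted = observed[np.asarray(mask, bool)], predicted[np.asarray(mask, bool)]
    if len(observed) < 2:
        raise ValueError("need at least 2 points")
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / len(observed)))
    if ss_tot == 0.0:
        return {"r2": float("nan"), "rmse": rmse, "degenerate": True}
    return {"r2": 1.0 - ss_res / ss_tot, "rmse": rmse, "degenerate": False}


def _finish(observed, drive, params, predicted, sse, frozen, free, config):
    mask = None if config.r2_all_cycles else drive.fit_mask
    gof = goodness_of_fit(observed, predicted.x_net, mask)
    return FitResult(
        params=params,
        predicted=predicted,
        r2=gof["r2"],
        rmse=gof["rmse"],
        objective=sse,
        frozen=tuple(frozen),
        free=tuple(free),
    )


# ---------------------------------------------------------------------------
# fit protocols
# ---------------------------------------------------------------------------

def fit_spe_only(
    observed: np.ndarray, drive: DriveSeries, config: FitConfig | None = None
) -> FitResult:
    """Fit the single SPE-driven process (free: A_SPE, B_SPE*SPE)."""
    config = config or FitConfig()
    mask = _check_series(observed, drive)
    y = np.asarray(observed, float)[mask]
    u = np.asarray(drive.spe_on, float)
    zero = np.zeros(mask.sum())

    def pq(a):
        return zero, _linear_trace(a, 1.0, u)[mask]

    a, b, sse = _profiled_fit(
        y, pq, config.retention_bounds, (0.0, config.drive_bound_deg), config
    )
    params = ModelParams(a_spe=a, b_spe=b)
    predicted = simulate_spe(params, drive)
    return _finish(observed, drive, params, predicted, sse, (), ("a_spe", "b_spe"), config)


def fit_independent_stage2(
    observed_miss: np.ndarray,
    drive: DriveSeries,
    frozen_spe: ModelParams,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the TPE process of the Independent Error model (free: A_TPE,
    B_TPE*TPE) with the SPE process frozen at its stage-1 estimates."""
    config = config or FitConfig()
    if frozen_spe.a_spe is None or frozen_spe.b_spe is None:
        raise ValueError("frozen_spe must carry a_spe and b_spe")
    mask = _check_series(observed_miss, drive)
    y = np.asarray(observed_miss, float)[mask]
    p_full = simulate_spe(frozen_spe, drive).x_net[mask]
    u = np.asarray(drive.tpe_on, float)

    def pq(a):
        return p_full, _linear_trace(a, 1.0, u)[mask]

    a, b, sse = _profiled_fit(
        y, pq, config.retention_bounds, (0.0, config.drive_bound_deg), config
    )
    params = ModelParams(
        a_spe=frozen_spe.a_spe, b_spe=frozen_spe.b_spe, a_tpe=a, b_tpe=b
    )
    predicted = simulate_independent(params, drive)
    return _finish(
        observed_miss, drive, params, predicted, sse,
        ("a_spe", "b_spe"), ("a_tpe", "b_tpe"), config,
    )


def _interaction_pq(g_a, a_spe, b_spe, drive):
    """Decompose the Interaction trace as p + g_b * q (affine in G_B)."""
    tpe = np.asarray(drive.tpe_on, bool)
    u = np.asarray(drive.spe_on, float)
    if not tpe.any():
        # gains apply on every cycle: constant-coefficient recursion
        q = _linear_trace(g_a * a_spe, b_spe, u)
        return np.zeros_like(q), q
    n = len(u)
    p = np.empty(n)
    q = np.empty(n)
    ps = qs = 0.0
    for i in range(n):
        a_i = a_spe if tpe[i] else g_a * a_spe
        ps = a_i * ps + (b_spe * u[i] if tpe[i] else 0.0)
        qs = a_i * qs + (0.0 if tpe[i] else b_spe * u[i])
        p[i], q[i] = ps, qs
    return p, q


def fit_interaction(
    observed: np.ndarray,
    drive: DriveSeries,
    config: FitConfig | None = None,
    frozen: ModelParams | None = None,
    estimate_gains: bool = False,
) -> FitResult:
    """Fit the Interaction model.

    Stage 1 (``estimate_gains=False``): free A_SPE, B_SPE*SPE with the gains
    pinned at 1.  Stage 2 (``estimate_gains=True``): free G_A, G_B with the
    dynamics frozen at the supplied stage-1 estimates.
    """
    config = config or FitConfig()
    mask = _check_series(observed, drive)
    y = np.asarray(observed, float)[mask]

    if not estimate_gains:
        # with both gains at 1 the model is the plain SPE recursion
        u = np.asarray(drive.spe_on, float)
        zero = np.zeros(mask.sum())

        def pq(a):
            return zero, _linear_trace(a, 1.0, u)[mask]

        a, b, sse = _profiled_fit(
            y, pq, config.retention_bounds, (0.0, config.drive_bound_deg), config
        )
        params = ModelParams(a_spe=a, b_spe=b, g_a=1.0, g_b=1.0)
        predicted = simulate_interaction(params, drive)
        return _finish(
            observed, drive, params, predicted, sse, (), ("a_spe", "b_spe"), config
        )

    if frozen is None or frozen.a_spe is None or frozen.b_spe is None:
        raise ValueError("estimate_gains=True requires frozen a_spe and b_spe")

    def pq(g_a):
        p, q = _interaction_pq(g_a, frozen.a_spe, frozen.b_spe, drive)
        return p[mask], q[mask]

    g_a, g_b, sse = _profiled_fit(y, pq, config.gain_bounds, config.gain_bounds, config)
    params = ModelParams(
        a_spe=frozen.a_spe, b_spe=frozen.b_spe, g_a=g_a, g_b=g_b
    )
    predicted = simulate_interaction(params, drive)
    return _finish(
        observed, drive, params, predicted, sse,
        ("a_spe", "b_spe"), ("g_a", "g_b"), config,
    )


# ---------------------------------------------------------------------------
# protocol descriptor + bootstrap
# ---------------------------------------------------------------------------

@dataclass
class FitSpec:
    """Names one fit protocol and its frozen inputs, for bootstrap refits."""

    protocol: str  # spe_only | independent_stage2 | interaction_stage1 | interaction_stage2
    drive: DriveSeries
    config: FitConfig = field(default_factory=FitConfig)
    frozen: ModelParams | None = None


def fit_by_spec(observed: np.ndarray, spec: FitSpec) -> FitResult:
    if spec.protocol == "spe_only":
        return fit_spe_only(observed, spec.drive, spec.config)
    if spec.protocol == "independent_stage2":
        return fit_independent_stage2(observed, spec.drive, spec.frozen, spec.config)
    if spec.protocol == "interaction_stage1":
        return fit_interaction(observed, spec.drive, spec.config, estimate_gains=False)
    if spec.protocol == "interaction_stage2":
        return fit_interaction(
            observed, spec.drive, spec.config, frozen=spec.frozen, estimate_gains=True
        )
    raise ValueError(f"unknown fit protocol {spec.protocol!r}")


def bootstrap_parameter_ci(
    subject_cycles: np.ndarray,
    fit_spec: FitSpec,
    n_boot: int = 10_000,
    seed: int = 0,
    keep_samples: bool = False,
) -> list[BootstrapCI]:
    """Percentile 95% CIs by resampling participants with replacement.

    ``subject_cycles`` is (n_subjects, n_cycles).  Each bootstrap draw
    resamples subjects, recomputes the group-mean cycle series and refits;
    frozen (stage-1) parameters stay at their full-sample values throughout.
    Deterministic given ``seed``.
    """
    subject_cycles = np.asarray(subject_cycles, dtype=float)
    if subject_cycles.ndim != 2 or subject_cycles.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_cycles) array")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n_subj = subject_cycles.shape[0]
    point = fit_by_spec(subject_cycles.mean(axis=0), fit_spec)
    free = point.free
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(free)))
    for b in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        res = fit_by_spec(subject_cycles[idx].mean(axis=0), fit_spec)
        draws[b] = [getattr(res.params, name) for name in free]
    out = []
    for j, name in enumerate(free):
        lo, hi = np.percentile(draws[:, j], [2.5, 97.5])
        out.append(
            BootstrapCI(
                parameter=name,
                estimate=float(getattr(point.params, name)),
                lo95=float(lo),
                hi95=float(hi),
                n_boot=n_boot,
                seed=seed,
                samples=draws[:, j].copy() if keep_samples else None,
            )
        )
    return out


def grid_search_spe_only(
    observed: np.ndarray,
    drive: DriveSeries,
    a_step: float = 0.01,
    b_step: float = 0.05,
    drive_bound_deg: float = 10.0,
) -> tuple[float, float, float]:
    """Exhaustive grid reference for the SPE-only fit (oracle, not the fitter).

    Returns (a, b, sse) at the best grid node; used to validate that the
    profiled optimizer attains at least the gridded optimum.
    """
    mask = _check_series(observed, drive)
    y = np.asarray(observed, float)[mask]
    u = np.asarray(drive.spe_on, float)
    best = (np.nan, np.nan, np.inf)
    for a in np.arange(0.0, 1.0 + a_step / 2, a_step):
        base = _linear_trace(a, 1.0, u)[mask]
        for b in np.arange(0.0, drive_bound_deg + b_step / 2, b_step):
            r = y - b * base
            sse = float(r @ r)
            if sse < best[2]:
                best = (float(a), float(b), sse)
    return best
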