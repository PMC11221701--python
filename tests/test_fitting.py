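"""Constrained fits: recovery, goodness of fit, grid oracle, bootstrap."""

import numpy as np
import pytest

from reachadapt import (
    FitConfig,
    FitSpec,
    ModelParams,
    bootstrap_parameter_ci,
    fit_by_spec,
    fit_independent_stage2,
    fit_interaction,
    fit_spe_only,
    goodness_of_fit,
    grid_search_spe_only,
    simulate_independent,
    simulate_interaction,
    simulate_spe,
)

from conftest import make_drive

TOL = 1e-5


def test_noiseless_spe_recovery(drives):
    drive = drives[("E1", "Hit")]
    truth = ModelParams(a_spe=0.7, b_spe=1.5)
    fit = fit_spe_only(simulate_spe(truth, drive).x_net, drive)
    assert fit.params.a_spe == pytest.approx(0.7, abs=TOL)
    assert fit.params.b_spe == pytest.approx(1.5, abs=TOL)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


def test_flat_zero_series_yields_zero_drive(drives):
    drive = drives[("E1", "Hit")]
    fit = fit_spe_only(np.zeros(len(drive)), drive)
    assert fit.params.b_spe == pytest.approx(0.0, abs=TOL)
    assert fit.objective == pytest.approx(0.0, abs=1e-12)


def test_noiseless_stage2_recovery(drives):
    drive = drives[("E1", "Miss")]
    frozen = ModelParams(a_spe=0.8184, b_spe=0.8441)
    truth = frozen.replace(a_tpe=0.6, b_tpe=3.0)
    y = simulate_independent(truth, drive).x_net
    fit = fit_independent_stage2(y, drive, frozen)
    assert fit.params.a_tpe == pytest.approx(0.6, abs=TOL)
    assert fit.params.b_tpe == pytest.approx(3.0, abs=TOL)
    assert fit.frozen == ("a_spe", "b_spe")


def test_stage2_on_spe_only_data_finds_no_tpe_drive(drives):
    drive = drives[("E1", "Miss")]
    frozen = ModelParams(a_spe=0.8184, b_spe=0.8441)
    y = simulate_spe(frozen, drive).x_net
    fit = fit_independent_stage2(y, drive, frozen)
    assert fit.params.b_tpe == pytest.approx(0.0, abs=TOL)


def test_interaction_stage1_and_stage2_recovery(drives):
    drive = drives[("E3", "ClampJump")]
    cfg = FitConfig(drive_bound_deg=30.0)
    frozen = ModelParams(a_spe=0.9199, b_spe=0.7181)
    truth = frozen.replace(g_a=1.02, g_b=0.7)
    y = simulate_interaction(truth, drive).x_net
    fit = fit_interaction(y, drive, cfg, frozen=frozen, estimate_gains=True)
    assert fit.params.g_a == pytest.approx(1.02, abs=1e-4)
    assert fit.params.g_b == pytest.approx(0.7, abs=1e-4)

    # stage 1 with unit gains is the plain SPE fit
    drive_c = drives[("E3", "Clamp")]
    y1 = simulate_interaction(frozen.replace(g_a=1.0, g_b=1.0), drive_c).x_net
    s1 = fit_interaction(y1, drive_c, cfg)
    assert s1.params.a_spe == pytest.approx(0.9199, abs=TOL)
    assert s1.params.b_spe == pytest.approx(0.7181, abs=TOL)


def test_stage2_identity_and_flat_cases(drives):
    drive = drives[("E1", "Hit")]
    frozen = ModelParams(a_spe=0.6735, b_spe=7.2607)
    y = simulate_interaction(frozen.replace(g_a=1.0, g_b=1.0), drive).x_net
    fit = fit_interaction(y, drive, frozen=frozen, estimate_gains=True)
    assert fit.params.g_a == pytest.approx(1.0, abs=1e-4)
    assert fit.params.g_b == pytest.approx(1.0, abs=1e-4)
    flat = fit_interaction(
        np.zeros(len(drive)), drive, frozen=frozen, estimate_gains=True
    )
    assert flat.params.g_b == pytest.approx(0.0, abs=TOL)


def test_estimate_gains_requires_frozen(drives):
    with pytest.raises(ValueError, match="frozen"):
        fit_interaction(
            np.zeros(len(drives[("E1", "Hit")])),
            drives[("E1", "Hit")],
            estimate_gains=True,
        )


def test_goodness_of_fit_hand_computed():
    perfect = goodness_of_fit([0, 2, 4], [0, 2, 4])
    assert perfect["r2"] == pytest.approx(1.0) and perfect["rmse"] == 0.0
    at_mean = goodness_of_fit([0, 2, 4], [2, 2, 2])
    assert at_mean["r2"] == pytest.approx(0.0)
    gof = goodness_of_fit([0, 2, 4], [0, 2, 3])
    assert gof["r2"] == pytest.approx(0.875)
    assert gof["rmse"] == pytest.approx(np.sqrt(1 / 3), abs=1e-4)
    degenerate = goodness_of_fit([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])
    assert degenerate["degenerate"] and np.isnan(degenerate["r2"])


def test_fit_rejects_misaligned_or_fully_masked(drives):
    drive = drives[("E1", "Hit")]
    with pytest.raises(ValueError):
        fit_spe_only(np.zeros(5), drive)
    empty = make_drive([1, 1, 1], mask=[False, False, False])
    with pytest.raises(ValueError, match="mask"):
        fit_spe_only(np.zeros(3), empty)


def test_fitter_attains_grid_search_optimum(rng):
    """Profiled constrained optimum is at least as good as an exhaustive
    grid (step 0.01 on retention, 0.05 on drive) on small problems."""
    for _ in range(6):
        n = int(rng.integers(5, 9))
        spe = (rng.random(n) < 0.7).astype(int)
        spe[0] = 1
        drive = make_drive(spe)
        truth = ModelParams(a_spe=rng.uniform(0, 1), b_spe=rng.uniform(0, 10))
        y = simulate_spe(truth, drive).x_net + rng.normal(0, 1.0, n)
        fit = fit_spe_only(y, drive)
        _, _, grid_sse = grid_search_spe_only(y, drive)
        assert fit.objective <= grid_sse + 1e-9


def test_nesting_releasing_parameters_never_hurts(drives, rng):
    """The stage-2 objective (gains free) cannot exceed the unit-gain
    objective of the same frozen dynamics."""
    drive = drives[("E1", "Hit")]
    frozen = ModelParams(a_spe=0.8, b_spe=0.9)
    y = simulate_spe(frozen, drive).x_net + rng.normal(0, 0.5, len(drive))
    pinned = simulate_interaction(frozen.replace(g_a=1.0, g_b=1.0), drive).x_net
    sse_pinned = float(np.sum((y - pinned)[drive.fit_mask] ** 2))
    free = fit_interaction(y, drive, frozen=frozen, estimate_gains=True)
    assert free.objective <= sse_pinned + 1e-9


def test_bootstrap_degenerate_identical_subjects(drives):
    drive = drives[("E1", "Hit")]
    truth = ModelParams(a_spe=0.8184, b_spe=0.8441)
    y = simulate_spe(truth, drive).x_net
    cohort = np.tile(y, (6, 1))
    cis = bootstrap_parameter_ci(
        cohort, FitSpec("spe_only", drive), n_boot=25, seed=0
    )
    for ci in cis:
        assert ci.lo95 == pytest.approx(ci.estimate, abs=1e-6)
        assert ci.hi95 == pytest.approx(ci.estimate, abs=1e-6)


def test_bootstrap_deterministic_and_validated(drives, rng):
    drive = drives[("E1", "Hit")]
    truth = ModelParams(a_spe=0.8184, b_spe=0.8441)
    cohort = simulate_spe(truth, drive).x_net + rng.normal(0, 1.5, (8, len(drive)))
    spec = FitSpec("spe_only", drive, FitConfig(n_starts=3, coarse_grid=21))
    a = bootstrap_parameter_ci(cohort, spec, n_boot=40, seed=11)
    b = bootstrap_parameter_ci(cohort, spec, n_boot=40, seed=11)
    assert [(c.lo95, c.hi95) for c in a] == [(c.lo95, c.hi95) for c in b]
    with pytest.raises(ValueError):
        bootstrap_parameter_ci(cohort, spec, n_boot=0, seed=1)
    with pytest.raises(ValueError):
        bootstrap_parameter_ci(cohort[:1], spec, n_boot=5, seed=1)


def test_fit_by_spec_dispatch_rejects_unknown(drives):
    with pytest.raises(ValueError, match="protocol"):
        fit_by_spec(np.zeros(32), FitSpec("nope", drives[("E1", "Hit")]))
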