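"""Trajectory preprocessing: filtering, onset/RT, deviation, exclusions,
baseline correction, cycles and phase windows."""

import numpy as np
import pytest

from reachadapt import (
    ModelParams,
    RawTrial,
    apply_exclusions,
    baseline_correct,
    build_schedule,
    cycle_average,
    hand_deviation_at_peak,
    lowpass_filter,
    movement_onset_rt,
    phase_metrics,
    preprocess_subject,
)
from reachadapt.design import Block
from reachadapt.kinematics import TrialMetrics, process_trial
from reachadapt.synthetic import GeneratorConfig, generate_raw_trials

FS = 100.0


def _trial(x, y, go=0.0):
    t = np.arange(len(x)) / FS
    return RawTrial(time=t, x=np.asarray(x, float), y=np.asarray(y, float),
                    go_cue_time=go)


def _straight_reach(angle_deg, n=120, speed=20.0, delay=30):
    """Hold at start for `delay` samples, then constant-speed straight path."""
    s = np.concatenate([np.zeros(delay), np.arange(n - delay) * speed / FS])
    th = np.radians(angle_deg)
    return _trial(s * np.cos(th), s * np.sin(th))


def test_filter_dc_gain_and_attenuation():
    const = _trial(np.full(200, 3.0), np.full(200, -2.0))
    out = lowpass_filter(const, 10.0)
    np.testing.assert_allclose(out.x, const.x, atol=1e-9)
    np.testing.assert_allclose(out.y, const.y, atol=1e-9)

    t = np.arange(1000) / FS
    slow = RawTrial(time=t, x=np.sin(2 * np.pi * 1.0 * t), y=np.zeros_like(t))
    fast = RawTrial(time=t, x=np.sin(2 * np.pi * 40.0 * t), y=np.zeros_like(t))
    mid = slice(200, 800)  # avoid edge transients
    assert np.ptp(lowpass_filter(slow, 10.0).x[mid]) > 0.99 * np.ptp(slow.x[mid])
    assert np.ptp(lowpass_filter(fast, 10.0).x[mid]) < 0.01 * np.ptp(fast.x[mid])


def test_filter_input_validation():
    with pytest.raises(ValueError, match="Nyquist"):
        lowpass_filter(_trial(np.zeros(50), np.zeros(50)), cutoff_hz=60.0)
    with pytest.raises(ValueError, match="8 samples"):
        lowpass_filter(_trial(np.zeros(4), np.zeros(4)))


def test_onset_is_first_five_percent_crossing():
    raw = _straight_reach(0.0, delay=30)
    res = movement_onset_rt(raw)
    assert not res["no_movement"]
    assert res["peak_speed"] == pytest.approx(20.0, rel=0.05)
    # constant-speed segment starts at sample 30; central differencing puts
    # the first crossing within one sample of it
    assert res["rt"] == pytest.approx(300.0, abs=1000.0 / FS)


def test_no_movement_and_zero_rt():
    still = _trial(np.zeros(100), np.zeros(100))
    assert movement_onset_rt(still)["no_movement"]
    raw = _straight_reach(0.0, delay=30)
    onset = movement_onset_rt(raw)["onset_time"]
    shifted = RawTrial(time=raw.time, x=raw.x, y=raw.y, go_cue_time=onset)
    assert movement_onset_rt(shifted)["rt"] == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("path,target,expected", [
    (100.0, 90.0, 10.0),
    (90.0, 90.0, 0.0),
    (80.0, 90.0, -10.0),
    (-170.0, 180.0, 10.0),  # wrap across the discontinuity
])
def test_hand_deviation_sign_convention(path, target, expected):
    raw = _straight_reach(path)
    assert hand_deviation_at_peak(raw, target) == pytest.approx(expected, abs=1e-9)


def test_deviation_exclusion_rule_strict_at_85():
    metrics = [
        TrialMetrics(90.0, 300.0, 30.0),
        TrialMetrics(85.0, 300.0, 30.0),
        TrialMetrics(-86.0, 300.0, 30.0),
        TrialMetrics(0.0, 300.0, 30.0),
    ]
    flagged, frac = apply_exclusions(metrics)
    assert [m.excluded for m in flagged] == [True, False, True, False]
    assert flagged[0].exclusion_reason == "deviation_gt_85"
    assert frac == pytest.approx(0.5)


def test_stylus_lift_marks_trial_bad():
    raw = _straight_reach(0.0)
    raw.stylus_lift = True
    m = process_trial(raw, 0.0)
    assert m.excluded and m.exclusion_reason == "stylus_lift"


def test_baseline_correction_linearity():
    schedule = build_schedule("E1", "Miss")
    n = schedule.n_trials
    dev = np.full(n, 2.0)
    learning = np.array([b is Block.LEARNING for b in schedule.blocks()])
    dev[learning] = 10.0
    corrected = baseline_correct(dev, schedule)
    assert corrected[~learning][0] == pytest.approx(0.0)
    assert corrected[learning][0] == pytest.approx(8.0)
    with pytest.raises(ValueError, match="baseline"):
        baseline_correct(np.full(n, np.nan), schedule)


def test_cycle_average_valid_trial_handling():
    vals = np.arange(240, dtype=float)
    means, n = cycle_average(vals)
    assert len(means) == 24 and (n == 10).all()
    np.testing.assert_allclose(means, vals.reshape(24, 10).mean(axis=1))

    vals = np.full(20, 5.0)
    vals[3] = np.nan  # one excluded trial -> mean over remaining 9
    means, n = cycle_average(vals)
    assert means[0] == pytest.approx(5.0) and n[0] == 9

    all_bad = np.full(10, np.nan)
    means, n = cycle_average(all_bad)
    assert np.isnan(means[0]) and n[0] == 0
    with pytest.raises(ValueError):
        cycle_average(np.zeros(15))


def test_phase_metrics_windows():
    schedule = build_schedule("E1", "Miss")
    n = schedule.n_trials
    flat = phase_metrics(np.zeros(n), np.full(n, 400.0), schedule)
    for field in ("early_learning", "late_learning", "early_nofb_washout",
                  "early_fb_washout", "late_washout", "rt_change_early"):
        assert getattr(flat, field) == pytest.approx(0.0)

    ramp = np.arange(n, dtype=float) / 10.0
    pm = phase_metrics(ramp, np.full(n, 400.0), schedule)
    learn_idx = np.nonzero([b is Block.LEARNING for b in schedule.blocks()])[0]
    assert pm.early_learning == pytest.approx(ramp[learn_idx[:10]].mean())
    assert pm.late_learning == pytest.approx(ramp[learn_idx[-10:]].mean())


def test_pipeline_recovers_programmed_aims_exactly():
    """Noise-free synthetic cohort: recovered deviations match the programmed
    aims to < 0.1 degree, RT to one sample period, with nothing excluded."""
    schedule = build_schedule("E1", "Miss")
    cfg = GeneratorConfig(
        generating_model="strategy_plus_spe",
        params=ModelParams(a_spe=0.8184, b_spe=0.8441),
        angular_noise_sd=0.0,
        n_subjects=1,
        seed=5,
    )
    cohort = generate_raw_trials(schedule, cfg)
    table, _ = preprocess_subject(cohort.subjects[0], schedule)
    truth = cohort.truth.query("subject == 1")
    assert not table["excluded"].any()
    assert np.max(np.abs(
        table["hand_dev_deg"].to_numpy() - truth["dev_norm_deg"].to_numpy()
    )) < 0.1
    assert np.max(np.abs(
        table["rt_ms"].to_numpy() - truth["rt_ms"].to_numpy()
    )) <= 1000.0 / cfg.sampling_rate
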