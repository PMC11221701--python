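import numpy as np
import pytest

from reachadapt import build_schedule, drive_sequence
from reachadapt.design import DriveSeries


@pytest.fixture(scope="session")
def schedules():
    """All eight designs, built once."""
    keys = [
        ("E1", "Hit"), ("E1", "Miss"), ("E2", "J10"), ("E2", "J20"),
        ("E3", "Clamp"), ("E3", "ClampJump"), ("E4", "J10CCW"), ("E4", "J30CW"),
    ]
    return {k: build_schedule(*k) for k in keys}


@pytest.fixture(scope="session")
def drives(schedules):
    return {k: drive_sequence(s) for k, s in schedules.items()}


def make_drive(spe, tpe=None, mask=None):
    """Small hand-made drive series for model unit tests."""
    spe = np.asarray(spe, int)
    n = len(spe)
    tpe = np.zeros(n, int) if tpe is None else np.asarray(tpe, int)
    mask = np.ones(n, bool) if mask is None else np.asarray(mask, bool)
    return DriveSeries(np.arange(1, n + 1), spe, tpe, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
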