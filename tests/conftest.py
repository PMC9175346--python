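import numpy as np
import pytest

import wcescreen as ws


@pytest.fixture(scope="session")
def basis6():
    """Six-month window, one interior knot (the small illustrative setting)."""
    return ws.make_basis(6, 1)


@pytest.fixture(scope="session")
def basis12():
    return ws.make_basis(12, 1)


@pytest.fixture(scope="session")
def acute_truth12():
    """Exponential-decay weight over 12 lags summing to log 3."""
    v = np.arange(1, 13, dtype=float)
    w = np.exp(-v / 3.0)
    w *= np.log(3.0) / w.sum()
    return ws.EventTruth("ACUTE", "ATC5", w, label="acute")


@pytest.fixture(scope="session")
def small_cohort(acute_truth12):
    """A 300-patient synthetic cohort with one acute code and two nulls."""
    T = 12
    codes = (
        acute_truth12,
        ws.EventTruth("N001", "ICD10", np.zeros(T), label="null"),
        ws.EventTruth("N002", "PROC", np.zeros(T), label="null"),
    )
    cfg = ws.SimConfig(
        n_patients=300,
        study_months=36,
        exposure=ws.ExposureModel(initiation=0.15),
        baseline_hazard=0.02,
        event_codes=codes,
        seed=11,
    )
    claims, demo, truth = ws.simulate_cohort(cfg)
    return cfg, claims, demo, truth
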