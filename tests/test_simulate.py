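import numpy as np
import pandas as pd
import pytest

import wcescreen as ws


def tiny_config(**kw):
    T = 6
    defaults = dict(
        n_patients=50,
        study_months=24,
        event_codes=(ws.EventTruth("E1", "ICD10", np.zeros(T)),),
        seed=1,
    )
    defaults.update(kw)
    return ws.SimConfig(**defaults)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            tiny_config(exposure=ws.ExposureModel(initiation=1.5))

    def test_study_shorter_than_twice_window_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            tiny_config(
                study_months=10,
                event_codes=(ws.EventTruth("E", "ICD10", np.zeros(6)),),
            )

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(baseline_hazard=-0.1)


class TestExposureProcess:
    def test_degenerate_always_initiate_always_persist(self):
        cfg = tiny_config(
            exposure=ws.ExposureModel(initiation=1.0, persistence=1.0),
            first_initiation_month=0,
        )
        panel = ws.simulate_panel(cfg)
        assert (panel.index_months == 0).all()
        for d in panel.doses:
            assert d.all() and d.size == cfg.study_months

    def test_zero_persistence_single_dispensing_month(self):
        cfg = tiny_config(exposure=ws.ExposureModel(persistence=0.0))
        panel = ws.simulate_panel(cfg)
        for d in panel.doses:
            assert d.sum() == 1 and d[0] == 1

    def test_every_patient_exposed_at_least_once(self):
        panel = ws.simulate_panel(tiny_config())
        assert all(d[0] == 1 for d in panel.doses)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = tiny_config(n_patients=40)
        c1, d1, t1 = ws.simulate_cohort(cfg)
        c2, d2, t2 = ws.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        c1, *_ = ws.simulate_cohort(tiny_config(seed=1))
        c2, *_ = ws.simulate_cohort(tiny_config(seed=2))
        assert not c1.equals(c2)


class TestSimulateEvents:
    def test_zero_multiplier_never_fires(self):
        truth = ws.EventTruth("E", "ICD10", np.ones(6), baseline_multiplier=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert ws.simulate_events(np.ones(20), truth, {}, 0.05, rng) is None

    def test_negative_baseline_rejected(self):
        truth = ws.EventTruth("E", "ICD10", np.zeros(6))
        with pytest.raises(ValueError):
            ws.simulate_events(np.ones(5), truth, {}, -0.01,
                               np.random.default_rng(0))

    def test_event_month_within_followup(self):
        truth = ws.EventTruth("E", "ICD10", np.full(6, 0.5))
        rng = np.random.default_rng(3)
        for _ in range(200):
            e = ws.simulate_events(np.ones(15), truth, {}, 0.05, rng)
            assert e is None or 1 <= e <= 15

    def test_null_rates_equal_in_exposed_and_unexposed_months(self):
        # true_weight == 0: empirical event rate must not depend on exposure
        T = 6
        truth = ws.EventTruth("E", "ICD10", np.zeros(T))
        cfg = ws.SimConfig(
            n_patients=2000, study_months=30, baseline_hazard=0.02,
            exposure=ws.ExposureModel(initiation=0.2, persistence=0.6,
                                      reinitiation=0.2),
            event_codes=(truth,), seed=12,
        )
        rng = np.random.default_rng(12)
        panel = ws.simulate_panel(cfg, rng)
        evm = ws.simulate_event_months(panel, truth, rng)
        events = {1: [0, 0], 0: [0, 0]}  # exposure -> [events, person-months]
        for i in range(panel.n):
            L = len(panel.doses[i]) if evm[i] == 0 else int(evm[i])
            for t in range(1, L + 1):
                x = int(panel.doses[i][t - 1])
                events[x][1] += 1
                if evm[i] == t:
                    events[x][0] += 1
        r1 = events[1][0] / events[1][1]
        r0 = events[0][0] / events[0][1]
        p = cfg.baseline_hazard
        se = np.sqrt(p / events[1][1] + p / events[0][1])
        assert abs(r1 - r0) < 4 * se

    def test_single_lag_truth_reproduces_hazard_ratio(self):
        # weight concentrated at lag 1: among single-dispensing patients the
        # dispensing-month hazard over the later-month hazard approximates
        # exp(w(1))
        T = 6
        w1 = 1.2
        truth = ws.EventTruth("E", "ICD10", np.r_[w1, np.zeros(T - 1)])
        cfg = ws.SimConfig(
            n_patients=4000, study_months=24, baseline_hazard=0.02,
            exposure=ws.ExposureModel(initiation=0.3, persistence=0.0),
            event_codes=(truth,), seed=5,
        )
        rng = np.random.default_rng(5)
        panel = ws.simulate_panel(cfg, rng)
        evm = ws.simulate_event_months(panel, truth, rng)
        ev_exposed = pm_exposed = ev_rest = pm_rest = 0
        for i in range(panel.n):
            L = len(panel.doses[i]) if evm[i] == 0 else int(evm[i])
            # single dispensing at t=1 only (persistence 0)
            pm_exposed += 1
            ev_exposed += evm[i] == 1
            pm_rest += L - 1
            ev_rest += evm[i] > 1
        h1 = ev_exposed / pm_exposed
        h0 = ev_rest / pm_rest
        # compare discrete hazards on the log scale within Monte-Carlo error
        log_hr = np.log(-np.log1p(-h1)) - np.log(-np.log1p(-h0))
        se = np.sqrt(1 / ev_exposed + 1 / ev_rest)
        assert abs(log_hr - w1) < 3 * se


class TestConservationInClaims:
    def test_event_records_never_precede_index(self, small_cohort):
        cfg, claims, demo, truth = small_cohort
        drug = claims[claims["code"] == cfg.drug_code]
        index = drug.groupby("patient_id")["month"].min()
        events = claims[claims["code_system"] != "ALD"]
        events = events[events["code"] != cfg.drug_code]
        for pid, grp in events.groupby("patient_id"):
            assert (grp["month"] >= index[pid]).all()


class TestTruthReport:
    def signal(self, rows):
        return pd.DataFrame(rows, columns=["code", "status"])

    def truth(self):
        return ws.truth_to_frame(
            (
                ws.EventTruth("A", "ATC5", np.full(3, 0.3), label="acute"),
                ws.EventTruth("N1", "ICD10", np.zeros(3), label="null"),
                ws.EventTruth("N2", "ICD10", np.zeros(3), label="null"),
            )
        )

    def test_perfect_recovery(self):
        sig = self.signal(
            [("A", "significant"), ("N1", "not significant"),
             ("N2", "not significant")]
        )
        rep = ws.truth_report(self.truth(), sig)
        m = ws.recovery_metrics(rep)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_empty_inputs_give_empty_report(self):
        rep = ws.truth_report(pd.DataFrame(), self.signal([]))
        assert rep.empty

    def test_unknown_code_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            ws.truth_report(self.truth(), self.signal([("ZZZ", "significant")]))

    def test_outcome_labels(self):
        sig = self.signal([("A", "not significant"), ("N1", "significant")])
        rep = ws.truth_report(self.truth(), sig).set_index("code")
        assert rep.loc["A", "outcome"] == "false-negative"
        assert rep.loc["N1", "outcome"] == "false-positive"
        assert rep.loc["N2", "outcome"] == "not evaluated"

    def test_weight_mae(self):
        sig = self.signal([("A", "significant")])
        rep = ws.truth_report(
            self.truth(), sig, fitted_weights={"A": np.full(3, 0.4)}
        ).set_index("code")
        assert rep.loc["A", "weight_mae"] == pytest.approx(0.1)
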