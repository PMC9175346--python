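import numpy as np
import pandas as pd
import pytest

import wcescreen as ws
from wcescreen.splines import SplineBasis


def brute_force_pseudo(doses, basis):
    """Independent double-loop oracle for Z_k(t) = sum_u B_k(t-u+1) x(u)."""
    T, K = basis.matrix.shape
    L = len(doses)
    Z = np.zeros((L, K))
    for t in range(1, L + 1):
        for u in range(1, t + 1):
            v = t - u + 1
            if v <= T:
                for k in range(K):
                    Z[t - 1, k] += basis.matrix[v - 1, k] * doses[u - 1]
    return Z


class TestPseudoCovariates:
    def test_zero_exposure_gives_zero(self, basis6):
        Z = ws.pseudo_covariates(np.zeros(10), basis6)
        assert np.all(Z == 0)

    def test_single_dose_reproduces_basis_row(self, basis6):
        x = np.zeros(8)
        x[0] = 1  # dose in month 1; at t=3 the lag is v = 3
        Z = ws.pseudo_covariates(x, basis6)
        np.testing.assert_allclose(Z[2], basis6.matrix[2], atol=1e-15)

    def test_matches_brute_force_on_random_series(self, basis6, basis12):
        rng = np.random.default_rng(123)
        for _ in range(100):
            basis = basis6 if rng.random() < 0.5 else basis12
            L = rng.integers(1, 20)
            x = rng.integers(0, 2, L).astype(float)
            Z = ws.pseudo_covariates(x, basis)
            np.testing.assert_allclose(Z, brute_force_pseudo(x, basis), atol=1e-12)

    def test_linear_predictor_equals_weighted_sum(self, basis6):
        # for any theta, sum_k theta_k Z_k(t) == sum_u w(t-u+1) x(u)
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 15).astype(float)
        theta = rng.normal(size=basis6.k)
        w = basis6.matrix @ theta
        Z = ws.pseudo_covariates(x, basis6)
        direct = np.convolve(x, w)[: x.size]
        np.testing.assert_allclose(Z @ theta, direct, atol=1e-12)


def _simulated_table(n=300, seed=5, truth=None, basis=None):
    T = 12
    basis = basis or ws.make_basis(T, 1)
    truth = truth or ws.EventTruth("E", "ATC5", np.zeros(T))
    cfg = ws.SimConfig(
        n_patients=n, study_months=36,
        exposure=ws.ExposureModel(initiation=0.15, persistence=0.7,
                                  reinitiation=0.3),
        baseline_hazard=0.02, event_codes=(truth,), seed=seed,
    )
    rng = np.random.default_rng(seed)
    panel = ws.simulate_panel(cfg, rng)
    evm = ws.simulate_event_months(panel, truth, rng)
    ppa = ws.build_arrays(panel.doses, evm, basis)
    return ppa, basis


class TestFitWce:
    def test_no_events_raises(self, basis12):
        table = pd.DataFrame(
            {"Id": [1, 1], "Start": [0, 1], "Stop": [1, 2], "Event": [0, 0]}
            | {f"Z{k}": [0.0, 0.0] for k in range(1, basis12.k + 1)}
        )
        with pytest.raises(ValueError, match="no events"):
            ws.fit_wce(table, basis12, min_events=0)

    def test_reduction_to_cumulative_dose_cox(self):
        # with a single constant basis column the WCE model is an ordinary
        # time-dependent Cox model on the rolling cumulative dose, so the
        # fit must agree with an independent Cox implementation
        from lifelines import CoxTimeVaryingFitter

        T = 12
        truth = ws.EventTruth("E", "ATC5", np.full(T, 0.08))
        cfg = ws.SimConfig(
            n_patients=200, study_months=36,
            exposure=ws.ExposureModel(initiation=0.15, persistence=0.7,
                                      reinitiation=0.3),
            baseline_hazard=0.02, event_codes=(truth,), seed=9,
        )
        rng = np.random.default_rng(9)
        panel = ws.simulate_panel(cfg, rng)
        evm = ws.simulate_event_months(panel, truth, rng)
        ones = _constant_basis(T)
        ppa = ws.build_arrays(panel.doses, evm, ones)
        fit = ws.fit_wce_arrays(ppa.start, ppa.stop, ppa.event, ppa.X, basis=ones)
        df = ws.frame_from_arrays(ppa).rename(
            columns={"Id": "id", "Start": "start", "Stop": "stop", "Event": "event"}
        )
        ctv = CoxTimeVaryingFitter()
        ctv.fit(df, id_col="id", event_col="event", start_col="start",
                stop_col="stop")
        ref = float(ctv.params_.iloc[0])
        assert abs(fit.theta[0] - ref) / abs(ref) < 1e-6

    def test_cloned_patients_double_loglik_same_estimate(self):
        # likelihood homogeneity holds exactly under Breslow ties (Efron's
        # tie fractions l/d change when every death is duplicated)
        ppa, basis = _simulated_table(
            n=150, seed=3, truth=ws.EventTruth("E", "ATC5", np.full(12, 0.05))
        )
        fit = ws.fit_wce_arrays(ppa.start, ppa.stop, ppa.event, ppa.X,
                                basis=basis, ties="breslow")
        twice = ws.PersonPeriodArrays(
            start=np.concatenate([ppa.start] * 2),
            stop=np.concatenate([ppa.stop] * 2),
            event=np.concatenate([ppa.event] * 2),
            X=np.vstack([ppa.X] * 2),
            row_offsets=np.concatenate(
                [ppa.row_offsets, ppa.row_offsets[1:] + ppa.row_offsets[-1]]
            ),
            basis=basis,
            covariate_names=(),
        )
        fit2 = ws.fit_wce_arrays(twice.start, twice.stop, twice.event, twice.X,
                                 basis=basis, ties="breslow")
        np.testing.assert_allclose(fit2.theta, fit.theta, atol=1e-6)
        # doubling rows doubles the likelihood up to the constant from the
        # doubled risk-set sums: ll' = 2 ll - 2 log(2) * n_events
        expected = 2 * fit.loglik - 2 * np.log(2) * fit.n_events
        assert fit2.loglik == pytest.approx(expected, rel=1e-8)

    def test_row_permutation_invariance(self):
        ppa, basis = _simulated_table(
            n=100, seed=4, truth=ws.EventTruth("E", "ATC5", np.full(12, 0.05))
        )
        fit = ws.fit_wce_arrays(ppa.start, ppa.stop, ppa.event, ppa.X, basis=basis)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ppa.start.size)
        fit_p = ws.fit_wce_arrays(
            ppa.start[perm], ppa.stop[perm], ppa.event[perm], ppa.X[perm],
            basis=basis,
        )
        np.testing.assert_allclose(fit_p.theta, fit.theta, atol=1e-8)

    def test_loglik_improves_over_null_and_score_vanishes(self):
        ppa, basis = _simulated_table(
            n=200, seed=6, truth=ws.EventTruth("E", "ATC5", np.full(12, 0.06))
        )
        res = ws.fit_cox(ppa.start, ppa.stop, ppa.event, ppa.X)
        assert res.converged
        assert res.loglik >= res.loglik_null
        assert np.max(np.abs(res.gradient)) < 1e-8


def _constant_basis(T):
    """A degenerate one-column basis: weight constant over all T lags, so
    the single pseudo-covariate is the rolling T-month cumulative dose."""
    ones = SplineBasis(window=T, nknots=0, constrained="none")
    object.__setattr__(ones, "matrix", np.ones((T, 1)))
    object.__setattr__(ones, "knots", np.array([1.0, float(T)]))
    return ones


class TestWeightAndWindowHr:
    def test_zero_theta_gives_unit_hr(self, basis12):
        fit = ws.WceFit(
            theta=np.zeros(basis12.k), gamma=np.zeros(0),
            weight=np.zeros(12), loglik=0.0, vcov=np.eye(basis12.k),
            window_hr=1.0, converged=True, n_events=10, basis=basis12,
        )
        assert ws.window_hr(fit) == pytest.approx(1.0)
        assert np.all(ws.weight_function(fit) == 0)

    def test_constant_weight_closed_form(self, basis12):
        # w(v) = log(2)/T for all lags => window HR exactly 2
        target = np.full(12, np.log(2) / 12)
        theta, *_ = np.linalg.lstsq(basis12.matrix, target, rcond=None)
        fit = ws.WceFit(
            theta=theta, gamma=np.zeros(0), weight=basis12.matrix @ theta,
            loglik=0.0, vcov=np.eye(basis12.k), window_hr=np.nan,
            converged=True, n_events=10, basis=basis12,
        )
        assert ws.window_hr(fit) == pytest.approx(2.0, rel=1e-10)
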