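"""Standing verification experiments.

Seeded simulation studies that measure the pipeline's operating
characteristics under its own generative model: weight-function recovery,
type-I error calibration of the bootstrap test, and the severity-denoising
contrast.  The experiment designs (sample sizes, exposure processes, event
rates) are fixed here and documented in docs/methods.md; the test suite
and scripts/acceptance.py both run these definitions.
"""

from __future__ import annotations

import numpy as np

from .bootstrap import bootstrap_association, select_signal
from .pperiod import build_arrays
from .screen import wce_signal_for_code
from .simulate import (CovariateModel, EventTruth, ExposureModel, SimConfig,
                       simulate_event_months, simulate_panel)
from .splines import make_basis
from .wce import fit_wce_arrays, pseudo_covariates

COVARIATES = ("age", "sex", "severity")


def exponential_decay_weight(window: int = 12, total_hr: float = 3.0,
                             scale: float = 3.0) -> np.ndarray:
    """Decaying lag-weight w(v) ∝ exp(-v/scale) with exp(Σw) = total_hr."""
    v = np.arange(1, window + 1, dtype=float)
    w = np.exp(-v / scale)
    w *= np.log(total_hr) / w.sum()
    return w


def brute_force_pseudo(doses, basis) -> np.ndarray:
    """Triple-loop oracle for the pseudo-covariates Z_k(t)."""
    T, K = basis.matrix.shape
    L = len(doses)
    Z = np.zeros((L, K))
    for t in range(1, L + 1):
        for u in range(1, t + 1):
            v = t - u + 1
            if v <= T:
                Z[t - 1] += basis.matrix[v - 1] * doses[u - 1]
    return Z


def pseudo_covariate_max_error(n_series: int = 100, seed: int = 0) -> float:
    """Worst absolute deviation of Z from the brute-force double sum over
    random small exposure series (histories up to 10 patients x T<=12)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_series):
        T = int(rng.integers(6, 13))
        m = int(rng.integers(0, min(3, T - 5) + 1))
        basis = make_basis(T, m)
        for _ in range(int(rng.integers(1, 11))):  # up to 10 patients
            L = int(rng.integers(1, 25))
            x = rng.integers(0, 2, L).astype(float)
            err = np.max(np.abs(pseudo_covariates(x, basis)
                                - brute_force_pseudo(x, basis)))
            worst = max(worst, float(err))
    return worst


# -- weight recovery ---------------------------------------------------------

RECOVERY = dict(
    n_patients=2000, study_months=48, window=12,
    persistence=0.5, reinitiation=0.5, baseline=0.02,
    constrained="right", n_repeats=10,
)


def weight_recovery(seed: int = 0, n_repeats: int | None = None) -> dict:
    """Re-estimate a known decaying weight function on simulated cohorts.

    Returns per-repeat weight correlations and window HRs plus their
    aggregates (mean correlation, geometric-mean HR); truth total HR is 3.
    """
    p = RECOVERY
    reps = p["n_repeats"] if n_repeats is None else n_repeats
    w_true = exponential_decay_weight(p["window"], total_hr=3.0)
    truth = EventTruth("ACUTE", "ATC5", w_true, label="acute")
    basis = make_basis(p["window"], 1, p["constrained"])
    seeds = [int(s) for s in
             np.random.SeedSequence(seed).generate_state(reps) % (2**31)]
    corrs, hrs = [], []
    for s in seeds:
        cfg = SimConfig(
            n_patients=p["n_patients"], study_months=p["study_months"],
            exposure=ExposureModel(persistence=p["persistence"],
                                   reinitiation=p["reinitiation"]),
            baseline_hazard=p["baseline"], event_codes=(truth,), seed=s,
        )
        rng = np.random.default_rng(s)
        panel = simulate_panel(cfg, rng)
        evm = simulate_event_months(panel, truth, rng)
        ppa = build_arrays(
            panel.doses, evm, basis,
            covariate_matrix=panel.covariate_matrix(),
            covariate_names=COVARIATES,
        )
        fit = fit_wce_arrays(ppa.start, ppa.stop, ppa.event, ppa.X,
                             basis=basis, covariate_names=COVARIATES)
        corrs.append(float(np.corrcoef(fit.weight, w_true)[0, 1]))
        hrs.append(float(fit.window_hr))
    return {
        "correlations": corrs,
        "window_hrs": hrs,
        "mean_correlation": float(np.mean(corrs)),
        "geometric_mean_hr": float(np.exp(np.mean(np.log(hrs)))),
        "true_hr": 3.0,
    }


# -- null calibration --------------------------------------------------------

CALIBRATION = dict(
    n_patients=500, study_months=36, initiation=0.3, window=12,
    n_codes=200, B=200, alpha=0.05,
)


def null_calibration(seed: int = 0, n_codes: int | None = None,
                     B: int | None = None) -> dict:
    """Type-I error of the bootstrap test over independent null codes.

    One cohort, many independent null event processes; reports the
    proportion of significant calls at the 5% level.
    """
    p = CALIBRATION
    n_codes = p["n_codes"] if n_codes is None else n_codes
    B = p["B"] if B is None else B
    null = EventTruth("NULL", "ICD10", np.zeros(p["window"]), label="null")
    cfg = SimConfig(
        n_patients=p["n_patients"], study_months=p["study_months"],
        exposure=ExposureModel(initiation=p["initiation"]),
        event_codes=(null,), seed=seed,
    )
    rng = np.random.default_rng(seed)
    panel = simulate_panel(cfg, rng)
    C = panel.covariate_matrix()
    basis = make_basis(p["window"], 1)
    Zs = [pseudo_covariates(d, basis) for d in panel.doses]
    boot_seeds = np.random.SeedSequence([seed, 1]).generate_state(n_codes)
    n_sig = n_skip = 0
    for c in range(n_codes):
        evm = simulate_event_months(panel, null, rng)
        _, _, status = wce_signal_for_code(
            panel.doses, evm, basis, covariate_matrix=C,
            covariate_names=COVARIATES, Z_list=Zs,
            B=B, alpha=p["alpha"], seed=int(boot_seeds[c]),
        )
        n_sig += status == "significant"
        n_skip += status in ("not evaluated", "non-estimable")
    return {
        "n_codes": n_codes,
        "n_significant": n_sig,
        "n_not_evaluated": n_skip,
        "proportion_significant": n_sig / n_codes,
        "alpha": p["alpha"],
    }


# -- severity denoising ------------------------------------------------------

DENOISING = dict(
    n_patients=400, study_months=48, initiation=0.3, persistence=0.85,
    severity_persistence_logodds=2.5, severity_log_hr=1.0, baseline=0.008,
    window=12, B=100, n_repeats=100, alpha=0.05,
)


def denoising_contrast(seed: int = 0, n_repeats: int | None = None) -> dict:
    """False positives on a severity-confounded null code, screened with
    and without the severity covariate.

    Severity lengthens exposure (persistence shift) and raises the event
    hazard, so the code is marginally associated with exposure; adjusting
    for severity should absorb the confounding.
    """
    p = DENOISING
    reps = p["n_repeats"] if n_repeats is None else n_repeats
    conf = EventTruth(
        "Z99", "ICD10", np.zeros(p["window"]),
        covariate_log_hazards={"severity": p["severity_log_hr"]},
        label="confounded-null",
    )
    basis = make_basis(p["window"], 1)
    rep_seeds = [int(s) for s in
                 np.random.SeedSequence([seed, 2]).generate_state(reps) % (2**31)]
    fp_with = fp_without = 0
    for s in rep_seeds:
        cfg = SimConfig(
            n_patients=p["n_patients"], study_months=p["study_months"],
            exposure=ExposureModel(initiation=p["initiation"],
                                   persistence=p["persistence"]),
            covariates=CovariateModel(
                severity_persistence_logodds=p["severity_persistence_logodds"]
            ),
            baseline_hazard=p["baseline"], event_codes=(conf,), seed=s,
        )
        rng = np.random.default_rng(s)
        panel = simulate_panel(cfg, rng)
        C = panel.covariate_matrix()
        Zs = [pseudo_covariates(d, basis) for d in panel.doses]
        evm = simulate_event_months(panel, conf, rng)
        _, _, adj = wce_signal_for_code(
            panel.doses, evm, basis, covariate_matrix=C,
            covariate_names=COVARIATES, Z_list=Zs,
            B=p["B"], alpha=p["alpha"], seed=s,
        )
        _, _, unadj = wce_signal_for_code(
            panel.doses, evm, basis, covariate_matrix=C[:, :2],
            covariate_names=COVARIATES[:2], Z_list=Zs,
            B=p["B"], alpha=p["alpha"], seed=s,
        )
        fp_with += adj == "significant"
        fp_without += unadj == "significant"
    return {
        "n_repeats": reps,
        "false_positives_with_severity": fp_with,
        "false_positives_without_severity": fp_without,
    }
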