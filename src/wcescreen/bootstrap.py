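"""Bootstrap association test for the WCE exposure effect.

The WCE model was designed to estimate a known exposure-risk function, not
to test for association, so the screen needs its own test: patients are
resampled with replacement (all of a patient's person-period rows move
together), the model is refitted on each replicate, and the log window
hazard ratio — the sum of the fitted weight function — is collected.
Percentile confidence intervals use the order statistics at ranks
j = [alpha/2 * B] and k = [(1 - alpha/2) * B] (1-based), and the two-sided
p-value is the doubled bootstrap tail proportion with a 1/B floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pperiod import PersonPeriodArrays
from .wce import WceFit, fit_wce_arrays

#: Replicate failure fraction above which the result is flagged unreliable.
MAX_FAILED_FRACTION = 0.2


@dataclass
class BootstrapResult:
    estimate: float  # log window HR on the original data
    replicates: np.ndarray  # converged replicate statistics
    B: int  # replicates requested
    alpha: float
    ci: tuple  # percentile CI on the log window HR scale
    p_value: float
    n_failed: int
    unreliable: bool
    seed: int | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def hr_ci(self) -> tuple:
        return (float(np.exp(self.ci[0])), float(np.exp(self.ci[1])))


def bootstrap_replicates(
    ppa: PersonPeriodArrays,
    B: int,
    seed,
    init: np.ndarray | None = None,
) -> tuple:
    """Refit the WCE model on B patient-level resamples.

    Returns (replicate log window HRs from converged refits, n_failed).
    The fitted coefficients of the original data may be passed as ``init``
    to warm-start each refit; the optimum is unchanged.
    """
    rng = np.random.default_rng(seed)
    n = ppa.n_patients
    wsum = ppa.basis.matrix.sum(axis=0)  # maps theta to log window HR
    K = ppa.basis.k
    stats = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sample = ppa.resample(idx)
        if sample.n_events == 0:
            n_failed += 1
            continue
        try:
            fit = fit_wce_arrays(
                sample.start, sample.stop, sample.event, sample.X,
                basis=ppa.basis, covariate_names=ppa.covariate_names,
                init=init,
            )
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        stats.append(float(wsum @ fit.theta))
    return np.asarray(stats), n_failed


def percentile_ci(replicates: np.ndarray, alpha: float) -> tuple:
    """Percentile confidence interval from bootstrap replicates.

    Bounds are the 1-based order statistics at ranks j = [alpha/2 * B] and
    k = [(1 - alpha/2) * B] (floor brackets), j clamped to at least 1.
    """
    r = np.sort(np.asarray(replicates, dtype=float))
    B = r.size
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if B < math.ceil(2.0 / alpha):
        raise ValueError(f"too few replicates ({B}) for alpha={alpha}")
    j = max(1, math.floor(alpha / 2.0 * B))
    k = max(1, math.floor((1.0 - alpha / 2.0) * B))
    return (float(r[j - 1]), float(r[k - 1]))


def bootstrap_pvalue(replicates: np.ndarray, null: float = 0.0) -> float:
    """Two-sided bootstrap p-value: doubled tail proportion, floored at 1/B."""
    r = np.asarray(replicates, dtype=float)
    B = r.size
    if B < 50:
        raise ValueError(f"need at least 50 replicates for a p-value, got {B}")
    lo = int(np.sum(r <= null))
    hi = int(np.sum(r >= null))
    p = 2.0 * min(lo, hi) / B
    return float(min(1.0, max(1.0 / B, p)))


def bootstrap_association(
    ppa: PersonPeriodArrays,
    fit: WceFit,
    B: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> BootstrapResult:
    """Full association test for one event code.

    ``fit`` is the WCE fit on the original table; the returned result holds
    the percentile CI and p-value of the log window HR over ``B`` patient
    resamples.  Non-converged replicates are excluded and counted; if more
    than 20% fail the result is flagged unreliable (and the screen reports
    the code as not evaluated).
    """
    init = np.concatenate([fit.theta, fit.gamma])
    reps, n_failed = bootstrap_replicates(ppa, B, seed, init=init)
    unreliable = n_failed > MAX_FAILED_FRACTION * B
    if reps.size >= math.ceil(2.0 / alpha):
        ci = percentile_ci(reps, alpha)
    else:
        ci = (float("nan"), float("nan"))
        unreliable = True
    p = bootstrap_pvalue(reps) if reps.size >= 50 else float("nan")
    return BootstrapResult(
        estimate=fit.log_window_hr,
        replicates=reps,
        B=B,
        alpha=alpha,
        ci=ci,
        p_value=p,
        n_failed=n_failed,
        unreliable=unreliable,
        seed=seed if isinstance(seed, int) else None,
    )


def select_signal(result: BootstrapResult, alpha: float | None = None) -> str:
    """Classify one code from its bootstrap result.

    Significant iff the percentile CI for the log window HR excludes 0.
    No multiple-testing correction is applied here (the screen is
    exploratory); Benjamini-Hochberg is available at the screening layer.
    """
    if result.unreliable or not np.isfinite(result.ci[0]):
        return "not evaluated"
    if alpha is not None and alpha != result.alpha:
        ci = percentile_ci(result.replicates, alpha)
    else:
        ci = result.ci
    return "significant" if (ci[0] > 0.0 or ci[1] < 0.0) else "not significant"
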