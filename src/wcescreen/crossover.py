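"""Case-crossover comparator: 1 risk period, 3 control periods, 1-month washouts.

Each patient with an incident event is their own control: exposure to the
drug of interest in the period just before the event is compared with
exposure in three earlier same-length periods, separated by one-month
washouts.  The design is immune to time-invariant confounding.  The odds
ratio is estimated by conditional logistic maximum likelihood on the 1:3
matched sets; period length is varied over 3/6/9 months as a sensitivity
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

_N_PERIODS = 4  # 1 risk + 3 controls
_BETA_BOUND = 15.0


@dataclass(frozen=True)
class CcoDesign:
    period_len: int = 3
    n_controls: int = 3
    washout: int = 1

    def __post_init__(self):
        if self.period_len <= 0:
            raise ValueError("period_len must be positive")
        if self.n_controls != 3 or self.washout != 1:
            raise ValueError("design is fixed at 3 control periods and 1-month washout")

    @property
    def span(self) -> int:
        """Months of pre-event history the full layout needs: 4L + 3."""
        return (self.n_controls + 1) * self.period_len + self.n_controls * self.washout


@dataclass(frozen=True)
class MatchedSet:
    patient_id: object
    code: str
    risk_exposed: int
    control_exposed: tuple

    def __post_init__(self):
        if len(self.control_exposed) != 3:
            raise ValueError("exactly three control periods required")
        vals = (self.risk_exposed, *self.control_exposed)
        if any(v not in (0, 1) for v in vals):
            raise ValueError("exposure indicators must be 0/1")

    @property
    def n_exposed(self) -> int:
        return self.risk_exposed + sum(self.control_exposed)

    @property
    def informative(self) -> bool:
        return 0 < self.n_exposed < _N_PERIODS


@dataclass
class CcoResult:
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_sets: int
    n_informative: int
    status: str  # "ok" | "non-estimable" | "no information"


def build_periods(event_month: int, design: CcoDesign) -> list:
    """The four half-open month ranges (lower open, upper closed).

    Risk period ends at the event month; control periods alternate with
    one-month washouts going backwards:

        risk      = (e - L,       e]
        control_1 = (e - 2L - 1,  e - L - 1]
        control_2 = (e - 3L - 2,  e - 2L - 2]
        control_3 = (e - 4L - 3,  e - 3L - 3]
    """
    e, L = int(event_month), design.period_len
    periods = [(e - L, e)]
    for i in range(1, design.n_controls + 1):
        hi = e - i * L - i * design.washout
        periods.append((hi - L, hi))
    return periods


def exposure_in_period(exposed_months, period: tuple) -> int:
    """1 iff any dispensing month m satisfies lo < m <= hi."""
    lo, hi = period
    m = np.asarray(exposed_months)
    return int(np.any((m > lo) & (m <= hi)))


def build_matched_set(
    patient_id,
    code: str,
    event_month: int,
    exposed_months,
    design: CcoDesign,
    observation_start: int = 0,
) -> MatchedSet | None:
    """Matched set for one case, or None if the layout is not observable.

    The full layout needs 4L + 3 months of observed history before the
    event; periods before the drug's index date are legitimate (exposure
    there is simply 0), only periods before the patient's observation start
    exclude the set.
    """
    if event_month - observation_start < design.span:
        return None
    periods = build_periods(event_month, design)
    flags = [exposure_in_period(exposed_months, p) for p in periods]
    return MatchedSet(
        patient_id=patient_id,
        code=code,
        risk_exposed=flags[0],
        control_exposed=tuple(flags[1:]),
    )


def _loglik_terms(sets):
    """(x_risk, a) per informative set; a = exposed periods out of 4."""
    xr = np.array([s.risk_exposed for s in sets if s.informative], dtype=float)
    a = np.array([s.n_exposed for s in sets if s.informative], dtype=float)
    return xr, a


def conditional_loglik(beta: float, xr: np.ndarray, a: np.ndarray) -> float:
    return float(np.sum(beta * xr - np.log(a * np.exp(beta) + (_N_PERIODS - a))))


def conditional_logistic_or(sets, alpha: float = 0.05) -> CcoResult:
    """Conditional logistic ML for 1:3 matched sets with binary exposure.

    Each informative set contributes exp(beta * x_risk) / sum over the four
    periods of exp(beta * x_period); concordant sets carry no information.
    Separation (all informative cases exposed, or none) is reported as
    non-estimable rather than a divergent estimate.
    """
    n_sets = len(sets)
    xr, a = _loglik_terms(sets)
    n_inf = xr.size
    if n_inf == 0:
        raise ValueError("no information: all matched sets are concordant")
    nan = float("nan")
    if np.all(xr == 1) or np.all(xr == 0):
        return CcoResult(nan, nan, nan, nan, nan, nan, n_sets, n_inf, "non-estimable")
    beta = 0.0
    for _ in range(100):
        ez = a * np.exp(beta)
        pi = ez / (ez + (_N_PERIODS - a))
        score = float(np.sum(xr - pi))
        # observed information: a(4-a) e^b / (a e^b + 4-a)^2 per set
        info = float(np.sum(a * (_N_PERIODS - a) * np.exp(beta)
                            / (ez + (_N_PERIODS - a)) ** 2))
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(score) < 1e-10:
            break
        if abs(beta) > _BETA_BOUND:
            return CcoResult(
                nan, nan, nan, nan, nan, nan, n_sets, n_inf, "non-estimable"
            )
    ez = a * np.exp(beta)
    info = float(np.sum(a * (_N_PERIODS - a) * np.exp(beta)
                        / (ez + (_N_PERIODS - a)) ** 2))
    se = 1.0 / math.sqrt(info)
    z = norm.ppf(1.0 - alpha / 2.0)
    p = 2.0 * float(norm.sf(abs(beta) / se))
    return CcoResult(
        beta=float(beta),
        se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=p,
        n_sets=n_sets,
        n_informative=n_inf,
        status="ok",
    )


def sensitivity_runs(
    cases: dict,
    exposed_months_by_patient: dict,
    code: str,
    durations=(3, 6, 9),
    observation_start: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Case-crossover results for each candidate period duration.

    Parameters
    ----------
    cases : dict patient_id -> event month (global month offsets)
    exposed_months_by_patient : dict patient_id -> dispensing months
    durations : iterable of period lengths in months

    Returns one row per duration with OR, Wald CI, p, set counts and the
    number of sets excluded for insufficient pre-event history.
    """
    rows = []
    for L in durations:
        design = CcoDesign(period_len=int(L))
        sets, n_excluded = [], 0
        for pid, e in cases.items():
            s = build_matched_set(
                pid, code, e, exposed_months_by_patient.get(pid, ()), design,
                observation_start,
            )
            if s is None:
                n_excluded += 1
            else:
                sets.append(s)
        row = {
            "code": code,
            "duration": int(L),
            "n_cases": len(cases),
            "n_sets": len(sets),
            "n_excluded": n_excluded,
        }
        try:
            res = conditional_logistic_or(sets, alpha=alpha)
            row.update(
                OR=res.odds_ratio, ci_low=res.ci_low, ci_high=res.ci_high,
                p=res.p_value, status=res.status,
            )
        except ValueError:
            row.update(
                OR=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                p=float("nan"), status="no information",
            )
        rows.append(row)
    return pd.DataFrame(rows)
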