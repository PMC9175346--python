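"""Seeded synthetic claims generator with known ground truth.

Emulates the statistical structure the screening pipeline assumes: a
case-only cohort of new users of a drug of interest, monthly binary exposure
trajectories (one treatment episode with configurable persistence), baseline
covariates (age, sex, and a binary disease-severity flag that lengthens
exposure), and first-occurrence event streams whose discrete-time hazards
follow known lag-weight functions.

The generative event model is the discrete-time analogue of the WCE Cox
model: in follow-up month t the event probability is

    p(t) = 1 - exp( -lambda0 * m * exp( sum_v w(v) x(t-v+1) + gamma' C ) )

with first event only, so the fitted model is correctly specified and
parameter recovery is a clean end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import from_month_offset

DRUG_CODE_DEFAULT = "DRUG001"
SEVERITY_CERT_CODES = ("SEV-A", "SEV-B")
#: mean gap (months) between routine-care contact records; these emulate the
#: steady stream of visits/lab reimbursements in real claims so that
#: "last record" censoring tracks true end of observation
VISIT_MEAN_GAP = 3.0


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class ExposureModel:
    """One treatment episode per patient.

    ``initiation`` is the per-month probability of starting the drug (from
    ``first_initiation_month`` onward, truncated so every patient initiates
    in-study: the cohort is case-only).  After initiation exposure follows a
    two-state Markov chain by month: an exposed month is followed by another
    with probability ``persistence`` (on the logit scale, shifted by the
    severity effect); an unexposed month restarts therapy with probability
    ``reinitiation``.  The default 0 gives one treatment episode per
    patient; positive values give the intermittent dispensing patterns that
    identify the full lag-weight function in recovery experiments.
    """

    initiation: float = 0.02
    persistence: float = 0.9
    reinitiation: float = 0.0


@dataclass(frozen=True)
class CovariateModel:
    age_mean: float = 54.8
    age_sd: float = 16.2
    p_female: float = 0.78
    p_severe: float = 0.35
    #: log-odds shift of monthly persistence for severe patients; this is
    #: what makes severity a confounder for severity-linked event codes.
    severity_persistence_logodds: float = 1.5


@dataclass(frozen=True)
class EventTruth:
    """Ground truth for one candidate event code.

    ``true_weight[v-1]`` is the log-hazard contribution of exposure v months
    ago; a null code has an all-zero weight, a severity-confounded null code
    additionally has a nonzero severity entry in ``covariate_log_hazards``.
    """

    code: str
    code_system: str
    true_weight: np.ndarray
    covariate_log_hazards: dict = field(default_factory=dict)
    baseline_multiplier: float = 1.0
    label: str = ""

    def __post_init__(self):
        w = np.asarray(self.true_weight, dtype=float)
        object.__setattr__(self, "true_weight", w)
        if self.baseline_multiplier < 0:
            raise ValueError("baseline_multiplier must be >= 0")

    @property
    def is_null(self) -> bool:
        return bool(np.all(self.true_weight == 0.0))


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 2000
    study_months: int = 132  # 01/2008..12/2018 at the default origin
    exposure: ExposureModel = field(default_factory=ExposureModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    event_codes: tuple = ()
    baseline_hazard: float = 0.01  # per-month rate
    drug_code: str = DRUG_CODE_DEFAULT
    first_initiation_month: int = 12  # leaves a fully observed lookback year
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        _check_prob("initiation", self.exposure.initiation)
        _check_prob("persistence", self.exposure.persistence)
        _check_prob("reinitiation", self.exposure.reinitiation)
        _check_prob("p_female", self.covariates.p_female)
        _check_prob("p_severe", self.covariates.p_severe)
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")
        wlen = max((len(t.true_weight) for t in self.event_codes), default=0)
        if wlen and self.study_months < 2 * wlen:
            raise ValueError(
                "study_months must be at least twice the exposure window "
                f"({self.study_months} < 2*{wlen})"
            )
        if self.study_months < 2:
            raise ValueError("study_months must be >= 2")


def default_truth_catalog(window: int = 24, n_null: int = 20) -> tuple:
    """Truth catalog spanning the effect types the pipeline should separate.

    One acute short-decay code, one delayed-cumulative code, one
    severity-confounded null code, and ``n_null`` pure-null codes.
    """
    v = np.arange(1, window + 1, dtype=float)
    acute = np.exp(-(v - 1) / 2.0)
    acute *= np.log(3.0) / acute.sum()
    delayed = (v / window) ** 2
    delayed *= np.log(2.5) / delayed.sum()
    systems = ("ATC5", "ICD10", "PROC")
    catalog = [
        EventTruth("X01AA01", "ATC5", acute, label="acute"),
        EventTruth("X01AB02", "ATC5", delayed, label="cumulative"),
        EventTruth(
            "Z99", "ICD10", np.zeros(window),
            covariate_log_hazards={"severity": 0.8},
            label="confounded-null",
        ),
    ]
    for i in range(n_null):
        catalog.append(
            EventTruth(
                f"N{i + 1:03d}", systems[i % 3], np.zeros(window), label="null"
            )
        )
    return tuple(catalog)


@dataclass
class CohortPanel:
    """In-memory cohort: per-patient exposure series plus covariates."""

    doses: list  # list of 0/1 ndarrays, doses[i][t-1] for follow-up month t
    index_months: np.ndarray
    age: np.ndarray
    sex: np.ndarray  # 1 = female
    severity: np.ndarray
    config: SimConfig

    @property
    def n(self) -> int:
        return self.index_months.size

    def covariate_matrix(self, names=("age", "sex", "severity")) -> np.ndarray:
        return np.column_stack([getattr(self, n).astype(float) for n in names])


def _truncated_geometric(rng, p: float, high: int, size: int) -> np.ndarray:
    """Failure counts ~ Geometric(p) conditioned on being < high."""
    if p >= 1.0:
        return np.zeros(size, dtype=np.int64)
    if p <= 0.0:
        raise ValueError("initiation probability 0 cannot produce a case-only cohort")
    q = 1.0 - p
    u = rng.random(size)
    g = np.floor(np.log1p(-u * (1.0 - q**high)) / np.log(q)).astype(np.int64)
    return np.clip(g, 0, high - 1)


def simulate_panel(config: SimConfig, rng=None) -> CohortPanel:
    """Draw covariates, initiation months and exposure trajectories."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_patients
    cov = config.covariates
    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, n), 18.0, 95.0)
    sex = (rng.random(n) < cov.p_female).astype(np.int8)
    severity = (rng.random(n) < cov.p_severe).astype(np.int8)

    first = config.first_initiation_month
    span = config.study_months - first - 1
    if span < 1:
        raise ValueError("study too short for any post-lookback follow-up")
    index_months = first + _truncated_geometric(
        rng, config.exposure.initiation, span, n
    )

    base_logit = _logit(config.exposure.persistence)
    reinit = config.exposure.reinitiation
    doses = []
    for i in range(n):
        L = config.study_months - int(index_months[i])
        p_pers = _expit(base_logit + cov.severity_persistence_logodds * severity[i])
        x = np.zeros(L, dtype=np.int8)
        x[0] = 1
        u = rng.random(L - 1) if L > 1 else np.empty(0)
        if reinit == 0.0:
            # single treatment episode: vectorized geometric run length
            cont = u < p_pers
            run = np.flatnonzero(~cont)
            stop = (run[0] + 1) if run.size else L
            x[1:stop] = 1
        else:
            for t in range(1, L):
                p = p_pers if x[t - 1] else reinit
                x[t] = u[t - 1] < p
        doses.append(x)
    return CohortPanel(
        doses=doses, index_months=index_months, age=age, sex=sex,
        severity=severity, config=config,
    )


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def _expit(x: float) -> float:
    if x == np.inf:
        return 1.0
    if x == -np.inf:
        return 0.0
    return float(1.0 / (1.0 + np.exp(-x)))


def simulate_events(
    doses: np.ndarray,
    truth: EventTruth,
    covariates: dict,
    baseline: float,
    rng,
) -> int | None:
    """First event month (1-based, month 1 = index month) or None.

    Discrete-time hazard with complementary-log-log link: in month t,
    ``p(t) = 1 - exp(-baseline * multiplier * exp(eta(t)))`` where ``eta``
    sums the lag-weighted exposure history and the covariate effects.
    Follow-up stops at the first event, so at most one event per patient.
    """
    if baseline < 0:
        raise ValueError("baseline hazard must be >= 0")
    x = np.asarray(doses, dtype=float)
    L = x.size
    eta = np.convolve(x, truth.true_weight)[:L]
    for name, g in truth.covariate_log_hazards.items():
        eta = eta + g * float(covariates[name])
    lam = baseline * truth.baseline_multiplier * np.exp(eta)
    p = -np.expm1(-lam)
    u = rng.random(L)
    hits = np.flatnonzero(u < p)
    return int(hits[0] + 1) if hits.size else None


def simulate_event_months(panel: CohortPanel, truth: EventTruth, rng) -> np.ndarray:
    """Vector of first event months for every patient (0 = censored)."""
    cov_names = tuple(truth.covariate_log_hazards)
    out = np.zeros(panel.n, dtype=np.int64)
    for i in range(panel.n):
        covs = {name: getattr(panel, name)[i] for name in cov_names}
        e = simulate_events(
            panel.doses[i], truth, covs, panel.config.baseline_hazard, rng
        )
        out[i] = 0 if e is None else e
    return out


def simulate_cohort(config: SimConfig):
    """Generate (claims, demographics, truth) tables for a full cohort.

    Claims rows carry patient_id, date (first of month, ISO), month (offset
    from the study origin), code_system and code: dispensings of the drug of
    interest for every exposed month, severity-certification records before
    the index for severe patients, and one first-occurrence record per event
    code that fires.  Identical config and seed give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    rows = {"patient_id": [], "month": [], "code_system": [], "code": []}

    def add(pid, month, system, code):
        rows["patient_id"].append(pid)
        rows["month"].append(int(month))
        rows["code_system"].append(system)
        rows["code"].append(code)

    for i in range(panel.n):
        pid = i + 1
        idx = int(panel.index_months[i])
        if panel.severity[i]:
            add(pid, max(0, idx - 6), "ALD", SEVERITY_CERT_CODES[i % 2])
        for t in np.flatnonzero(panel.doses[i]):
            add(pid, idx + int(t), "ATC5", config.drug_code)
        # routine-care contacts from index to end of study; real claims are
        # dense with visit/lab reimbursements, so follow-up inferred from the
        # last record is non-informative about any one event process
        m = idx
        while True:
            m += 1 + int(rng.geometric(1.0 / VISIT_MEAN_GAP) - 1)
            if m >= config.study_months:
                break
            add(pid, m, "VISIT", "CONSULT")

    for truth in config.event_codes:
        months = simulate_event_months(panel, truth, rng)
        for i in np.flatnonzero(months):
            pid = i + 1
            add(pid, int(panel.index_months[i]) + int(months[i]) - 1,
                truth.code_system, truth.code)

    claims = pd.DataFrame(rows)
    claims["date"] = from_month_offset(claims["month"]).strftime("%Y-%m-%d")
    claims = claims.sort_values(
        ["patient_id", "month", "code_system", "code"], kind="stable"
    ).reset_index(drop=True)[["patient_id", "date", "code_system", "code", "month"]]

    origin_year = 2008
    index_year = origin_year + panel.index_months // 12
    demographics = pd.DataFrame(
        {
            "patient_id": np.arange(1, panel.n + 1),
            "sex": panel.sex,
            "birth_year": (index_year - np.round(panel.age)).astype(int),
            "death_date": pd.Series([pd.NA] * panel.n, dtype="string"),
            # age at index is kept explicitly so month-resolution rounding
            # in birth_year does not leak into the fitted covariate
            "age_at_index": np.round(panel.age, 1),
            "severity": panel.severity,
        }
    )
    truth_table = truth_to_frame(config.event_codes)
    return claims, demographics, truth_table


def truth_to_frame(event_codes) -> pd.DataFrame:
    recs = []
    for t in event_codes:
        rec = {
            "code": t.code,
            "code_system": t.code_system,
            "label": t.label,
            "is_null": t.is_null,
            "baseline_multiplier": t.baseline_multiplier,
            "gamma_severity": t.covariate_log_hazards.get("severity", 0.0),
        }
        for v, w in enumerate(t.true_weight, start=1):
            rec[f"w_{v}"] = w
        recs.append(rec)
    return pd.DataFrame(recs)


def truth_report(
    truth_table: pd.DataFrame,
    signal_table: pd.DataFrame,
    fitted_weights: dict | None = None,
) -> pd.DataFrame:
    """Score a screen against ground truth.

    Each code is labelled true-positive / false-positive / true-negative /
    false-negative from its true association status and the screen's
    significance call; codes the screen did not evaluate are labelled
    ``not evaluated``.  Optional ``fitted_weights`` (code -> array) adds the
    mean absolute error of the estimated weight function.

    Raises
    ------
    ValueError
        If the signal table mentions codes absent from the truth table.
    """
    if truth_table.empty and signal_table.empty:
        return pd.DataFrame(
            columns=["code", "truly_associated", "significant", "outcome", "weight_mae"]
        )
    known = set(truth_table["code"])
    extra = set(signal_table["code"]) - known if not signal_table.empty else set()
    if extra:
        raise ValueError(f"signal table contains unknown codes: {sorted(extra)}")
    status = (
        signal_table.set_index("code")["status"]
        if not signal_table.empty
        else pd.Series(dtype=object)
    )
    recs = []
    for _, row in truth_table.iterrows():
        code = row["code"]
        truly = not bool(row["is_null"])
        st = status.get(code, "not evaluated")
        if st in ("not evaluated", "non-estimable"):
            outcome = "not evaluated"
            sig = False
        else:
            sig = st == "significant"
            outcome = {
                (True, True): "true-positive",
                (True, False): "false-negative",
                (False, True): "false-positive",
                (False, False): "true-negative",
            }[(truly, sig)]
        mae = np.nan
        if fitted_weights and code in fitted_weights:
            west = np.asarray(fitted_weights[code], dtype=float)
            wtrue = row[[c for c in truth_table.columns if c.startswith("w_")]]
            wtrue = wtrue.to_numpy(dtype=float)[: west.size]
            mae = float(np.mean(np.abs(west - wtrue)))
        recs.append(
            {
                "code": code,
                "truly_associated": truly,
                "significant": sig,
                "outcome": outcome,
                "weight_mae": mae,
            }
        )
    return pd.DataFrame(recs)


def recovery_metrics(report: pd.DataFrame) -> dict:
    """Sensitivity/specificity/false-positive proportion from a truth report."""
    ev = report[report["outcome"] != "not evaluated"]
    pos = ev[ev["truly_associated"]]
    neg = ev[~ev["truly_associated"]]
    return {
        "sensitivity": float(pos["significant"].mean()) if len(pos) else np.nan,
        "specificity": float((~neg["significant"]).mean()) if len(neg) else np.nan,
        "false_positive_rate": float(neg["significant"].mean()) if len(neg) else np.nan,
        "n_evaluated": int(len(ev)),
    }
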