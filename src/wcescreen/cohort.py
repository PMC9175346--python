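"""New-user cohort construction and person-period tables from claims.

Claims are long tables (patient_id, date, code_system, code); dates are
converted to integer month offsets from a study origin.  Time zero for each
patient is the index month (first dispensing of the drug of interest), since
the exposure window of the WCE model is anchored to drug introduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PERSON_PERIOD_COLUMNS = ("Id", "Start", "Stop", "Event")


@dataclass(frozen=True)
class ExposureSeries:
    """Monthly binary exposure for one patient, anchored at the index month.

    ``doses[t-1]`` is 1 iff the patient had at least one dispensing of the
    drug of interest in follow-up month t (t = 1 is the index month, so
    ``doses[0] == 1`` always).
    """

    patient_id: object
    index_month: int
    doses: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=np.int8)
        if d.size == 0 or d[0] != 1:
            raise ValueError("exposure series must start with a dispensing month")
        if not np.isin(d, (0, 1)).all():
            raise ValueError("doses must be binary")
        object.__setattr__(self, "doses", d)

    @property
    def length(self) -> int:
        return int(self.doses.size)


def to_month_offset(dates, origin: str = "2008-01") -> np.ndarray:
    """Convert dates to integer month offsets from the study origin month."""
    p = pd.PeriodIndex(pd.to_datetime(dates), freq="M")
    o = pd.Period(origin, freq="M")
    return (p - o).map(lambda d: d.n).to_numpy(dtype=np.int64)


def from_month_offset(months, origin: str = "2008-01") -> pd.DatetimeIndex:
    """First day of each offset month (inverse of :func:`to_month_offset`)."""
    o = pd.Period(origin, freq="M")
    return pd.DatetimeIndex([(o + int(m)).to_timestamp() for m in np.asarray(months)])


def select_new_users(
    claims: pd.DataFrame, drug_code: str, lookback_months: int = 12
) -> pd.DataFrame:
    """Identify new users of the drug of interest and their index months.

    A patient is included iff the first in-study dispensing of ``drug_code``
    has (a) at least ``lookback_months`` fully observed months of data before
    it and (b) no dispensing of the same drug in that window.  Claims must
    carry a ``month`` column (offsets from the study origin, study start at
    month 0).

    Returns a DataFrame (patient_id, index_month), possibly empty.
    """
    if lookback_months < 1:
        raise ValueError("lookback_months must be >= 1")
    disp = claims.loc[claims["code"] == drug_code]
    if disp.empty:
        warnings.warn(f"drug code {drug_code!r} not found in claims; empty cohort")
        return pd.DataFrame({"patient_id": [], "index_month": []})
    first = disp.groupby("patient_id")["month"].min()
    # study data start at month 0: require a fully observed lookback window
    keep = first[first >= lookback_months]
    return keep.rename("index_month").reset_index()


def monthly_exposure(
    claims: pd.DataFrame, patient_id, index_month: int, end_of_followup: int
) -> ExposureSeries:
    """Binary per-month exposure from index to end of follow-up (inclusive).

    Multiple dispensings within a month collapse to 1.
    """
    if index_month > end_of_followup:
        raise ValueError("index month after end of follow-up")
    months = claims.loc[claims["patient_id"] == patient_id, "month"].to_numpy()
    L = end_of_followup - index_month + 1
    doses = np.zeros(L, dtype=np.int8)
    rel = months - index_month
    rel = rel[(rel >= 0) & (rel < L)]
    doses[rel] = 1
    return ExposureSeries(patient_id=patient_id, index_month=index_month, doses=doses)


def severity_flag(
    certifications: pd.DataFrame, severity_codes, index_months: pd.Series
) -> pd.Series:
    """Disease-severity indicator per patient.

    1 iff the patient has a chronic-disease certification for one of
    ``severity_codes`` dated at or before their index month.  ``index_months``
    is a Series indexed by patient_id; the result shares that index.
    """
    flags = pd.Series(0, index=index_months.index, dtype=np.int8)
    if certifications is None or certifications.empty:
        return flags
    hits = certifications.loc[certifications["code"].isin(set(severity_codes))]
    for pid, grp in hits.groupby("patient_id"):
        if pid in index_months.index and (grp["month"] <= index_months[pid]).any():
            flags[pid] = 1
    return flags


def censoring_month(
    patient_claims_months: np.ndarray,
    index_month: int,
    study_end: int,
    death_month: int | None = None,
) -> int:
    """End of a patient's follow-up: earliest of death, study end, and the
    last month with any claims record for the patient."""
    last_record = int(np.max(patient_claims_months))
    stop = min(study_end, last_record)
    if death_month is not None and not pd.isna(death_month):
        stop = min(stop, int(death_month))
    return max(stop, index_month)


def build_person_period(
    exposure: ExposureSeries,
    event_month: int | None,
    covariates: dict | None = None,
) -> pd.DataFrame:
    """Person-period rows for one patient and one candidate event code.

    One row per follow-up month, ``Start = t-1``, ``Stop = t`` (intervals
    closed on the right, first Start = 0 at the index month).  If
    ``event_month`` (months since index, 1-based) is given, follow-up stops
    there and the last row has Event = 1; otherwise all rows are censored.

    Raises
    ------
    ValueError
        If the event falls outside the observed follow-up (inconsistent
        input) or at/before the index month.
    """
    L = exposure.length
    if event_month is not None:
        if event_month < 1:
            raise ValueError(
                "event at or before the index month cannot be post-exposure"
            )
        if event_month > L:
            raise ValueError("event after censoring month: inconsistent input")
        n_rows = int(event_month)
    else:
        n_rows = L
    t = np.arange(1, n_rows + 1)
    ev = np.zeros(n_rows, dtype=np.int8)
    if event_month is not None:
        ev[-1] = 1
    out = {
        "Id": np.repeat(exposure.patient_id, n_rows),
        "Start": t - 1,
        "Stop": t,
        "Event": ev,
        "dose": exposure.doses[:n_rows].astype(np.int8),
    }
    for name, value in (covariates or {}).items():
        out[name] = np.repeat(value, n_rows)
    return pd.DataFrame(out)


def first_event_months(
    claims: pd.DataFrame, code_system: str, code: str
) -> pd.Series:
    """First occurrence month of one (code_system, code) per patient."""
    sel = claims.loc[(claims["code_system"] == code_system) & (claims["code"] == code)]
    return sel.groupby("patient_id")["month"].min()
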