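"""Compact array form of person-period tables for repeated fitting.

The bootstrap refits the WCE model on hundreds of patient resamples, so the
table is kept as flat arrays with contiguous per-patient row blocks; patient
resampling is then pure index arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import SplineBasis
from .wce import pseudo_covariates


@dataclass
class PersonPeriodArrays:
    """Stacked person-period rows with pseudo-covariates.

    ``X`` holds the K spline pseudo-covariates followed by the baseline
    covariates; rows of each patient are contiguous, delimited by
    ``row_offsets`` (length n_patients + 1).
    """

    start: np.ndarray
    stop: np.ndarray
    event: np.ndarray
    X: np.ndarray
    row_offsets: np.ndarray
    basis: SplineBasis
    covariate_names: tuple

    @property
    def n_patients(self) -> int:
        return self.row_offsets.size - 1

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def resample(self, patient_idx: np.ndarray) -> "PersonPeriodArrays":
        """Table for a with-replacement sample of patients (rows copied)."""
        off = self.row_offsets
        lengths = off[patient_idx + 1] - off[patient_idx]
        total = int(lengths.sum())
        firsts = np.repeat(off[patient_idx], lengths)
        csum = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        rows = firsts + (np.arange(total) - np.repeat(csum, lengths))
        new_off = np.concatenate([[0], np.cumsum(lengths)])
        return PersonPeriodArrays(
            start=self.start[rows],
            stop=self.stop[rows],
            event=self.event[rows],
            X=self.X[rows],
            row_offsets=new_off,
            basis=self.basis,
            covariate_names=self.covariate_names,
        )


def build_arrays(
    doses_list,
    event_months,
    basis: SplineBasis,
    covariate_matrix=None,
    covariate_names: tuple = (),
    Z_list=None,
    drop_index_month_events: bool = True,
) -> PersonPeriodArrays:
    """Assemble person-period arrays for one candidate event code.

    Parameters
    ----------
    doses_list : sequence of binary arrays
        Per-patient monthly exposure from the index month.
    event_months : array of int
        First event month per patient (1-based, month 1 = index month),
        0 for censored patients.
    covariate_matrix : ndarray (n_patients, c), optional
        Fixed baseline covariates replicated over each patient's rows.
    Z_list : optional precomputed pseudo-covariates per patient (full
        follow-up length); computed from ``doses_list`` when omitted.
    drop_index_month_events : bool
        Month granularity cannot order within-month occurrences, so events
        dated in the index month make the patient non-evaluable for the
        code; such patients are dropped.
    """
    event_months = np.asarray(event_months, dtype=np.int64)
    n = len(doses_list)
    if Z_list is None:
        Z_list = [pseudo_covariates(d, basis) for d in doses_list]
    starts, stops, events, Xs = [], [], [], []
    lengths = []
    for i in range(n):
        e = int(event_months[i])
        if e == 1 and drop_index_month_events:
            continue
        L = len(doses_list[i])
        n_rows = e if e > 0 else L
        if n_rows > L:
            raise ValueError("event after censoring month: inconsistent input")
        t = np.arange(1, n_rows + 1, dtype=float)
        ev = np.zeros(n_rows, dtype=np.int64)
        if e > 0:
            ev[-1] = 1
        Z = Z_list[i][:n_rows]
        if covariate_matrix is not None:
            C = np.broadcast_to(covariate_matrix[i], (n_rows, covariate_matrix.shape[1]))
            Xs.append(np.hstack([Z, C]))
        else:
            Xs.append(Z)
        starts.append(t - 1)
        stops.append(t)
        events.append(ev)
        lengths.append(n_rows)
    if not lengths:
        raise ValueError("no evaluable patients for this code")
    return PersonPeriodArrays(
        start=np.concatenate(starts),
        stop=np.concatenate(stops),
        event=np.concatenate(events),
        X=np.vstack(Xs),
        row_offsets=np.concatenate([[0], np.cumsum(lengths)]),
        basis=basis,
        covariate_names=tuple(covariate_names),
    )


def arrays_from_frame(
    table: pd.DataFrame, basis: SplineBasis, covariates: tuple = ()
) -> PersonPeriodArrays:
    """Convert a person-period DataFrame (with Z columns) to arrays."""
    zcols = [f"Z{k + 1}" for k in range(basis.k)]
    df = table.sort_values(["Id", "Start"], kind="stable")
    ids = df["Id"].to_numpy()
    boundaries = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    offsets = np.r_[boundaries, ids.size]
    return PersonPeriodArrays(
        start=df["Start"].to_numpy(dtype=float),
        stop=df["Stop"].to_numpy(dtype=float),
        event=df["Event"].to_numpy(dtype=np.int64),
        X=df[zcols + list(covariates)].to_numpy(dtype=float),
        row_offsets=offsets,
        basis=basis,
        covariate_names=tuple(covariates),
    )


def frame_from_arrays(ppa: PersonPeriodArrays, ids=None) -> pd.DataFrame:
    """Person-period DataFrame (Id, Start, Stop, Event, Z*, covariates)."""
    n_rows = ppa.start.size
    if ids is None:
        ids = np.arange(1, ppa.n_patients + 1)
    row_ids = np.repeat(ids, np.diff(ppa.row_offsets))
    data = {
        "Id": row_ids,
        "Start": ppa.start.astype(int),
        "Stop": ppa.stop.astype(int),
        "Event": ppa.event.astype(int),
    }
    K = ppa.basis.k
    for k in range(K):
        data[f"Z{k + 1}"] = ppa.X[:, k]
    for j, name in enumerate(ppa.covariate_names):
        data[name] = ppa.X[:, K + j]
    assert n_rows == row_ids.size
    return pd.DataFrame(data)
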