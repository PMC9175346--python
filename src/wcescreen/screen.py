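"""Screen every candidate health event against drug exposure.

For each distinct (code_system, code) observed in the cohort after the
index dispensing, the screen builds the incident-event person-period table,
fits the spline-weighted cumulative-exposure Cox model, runs the patient
bootstrap association test, and (optionally) the case-crossover comparator.
Codes are independent units with deterministically derived seeds, so the
output is identical regardless of execution order; a failure on one code is
logged and never aborts the screen.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from . import cohort as ch
from .bootstrap import bootstrap_association, select_signal
from .crossover import sensitivity_runs
from .pperiod import build_arrays
from .simulate import SEVERITY_CERT_CODES
from .splines import SplineBasis, make_basis
from .wce import fit_wce_arrays, pseudo_covariates

log = logging.getLogger("wcescreen")

SIGNAL_COLUMNS = (
    "code", "code_system", "label", "n_patients_evaluable", "n_events",
    "method", "HR", "ci_low", "ci_high", "p", "status",
)


@dataclass
class ScreenConfig:
    """Screening parameters; defaults follow the reference set-up
    (monthly periods, 24-month window, one interior knot, 1,000 bootstrap
    replicates, 5% level, age/sex/severity covariates, no multiple-testing
    correction)."""

    drug_code: str = "DRUG001"
    window: int = 24
    nknots: int = 1
    constrained: str = "none"
    bootstraps: int = 1000
    alpha: float = 0.05
    covariates: tuple = ("age", "sex", "severity")
    severity_codes: tuple = tuple(SEVERITY_CERT_CODES)
    lookback_months: int = 12
    study_months: int = 132
    methods: tuple = ("WCE", "CCO-3")
    min_events: int = 10
    ties: str = "efron"
    fdr: bool = False
    origin: str = "2008-01"
    seed: int = 0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def code_seed(master_seed: int, code_system: str, code: str) -> np.random.SeedSequence:
    """Deterministic per-code seed so screening order never matters."""
    tag = zlib.crc32(f"{code_system}:{code}".encode())
    return np.random.SeedSequence([int(master_seed), int(tag)])


def enumerate_candidates(claims: pd.DataFrame, drug_code: str) -> pd.DataFrame:
    """Every distinct (code_system, code) in the claims except the drug of
    interest itself, severity certifications and routine-contact records."""
    if claims.empty:
        return pd.DataFrame(columns=["code_system", "code"])
    cat = claims[["code_system", "code"]].drop_duplicates()
    cat = cat[(cat["code"] != drug_code)
              & (~cat["code_system"].isin(["ALD", "VISIT"]))]
    return cat.sort_values(["code_system", "code"]).reset_index(drop=True)


@dataclass
class _Cohort:
    """Materialized cohort: exposure series, pseudo-covariates, covariates."""

    patient_ids: np.ndarray
    index_months: np.ndarray
    doses: list
    Z: list
    covariate_matrix: np.ndarray
    covariate_names: tuple
    basis: SplineBasis
    drug_months: dict  # patient_id -> global dispensing months


def materialize_cohort(
    claims: pd.DataFrame, demographics: pd.DataFrame, config: ScreenConfig
) -> _Cohort:
    """Select new users and build everything the per-code loops reuse."""
    basis = make_basis(config.window, config.nknots, config.constrained)
    users = ch.select_new_users(claims, config.drug_code, config.lookback_months)
    study_end = config.study_months - 1
    demo = demographics.set_index("patient_id")
    index_by_pid = users.set_index("patient_id")["index_month"]
    severity = ch.severity_flag(
        claims[claims["code_system"] == "ALD"], config.severity_codes, index_by_pid
    )
    pids, idxs, doses, Zs, covs, drug_months = [], [], [], [], [], {}
    claims_by_pid = dict(tuple(claims.groupby("patient_id")))
    for pid, index_month in index_by_pid.items():
        pclaims = claims_by_pid[pid]
        death = None
        if "death_date" in demo.columns and pd.notna(demo.loc[pid, "death_date"]):
            death = int(ch.to_month_offset([demo.loc[pid, "death_date"]],
                                           config.origin)[0])
        censor = ch.censoring_month(
            pclaims["month"].to_numpy(), int(index_month), study_end, death
        )
        drug_rows = pclaims.loc[pclaims["code"] == config.drug_code, "month"]
        exp = ch.monthly_exposure(
            pclaims[pclaims["code"] == config.drug_code], pid,
            int(index_month), censor,
        )
        if "age_at_index" in demo.columns:
            age = float(demo.loc[pid, "age_at_index"])
        else:
            age = 2008 + index_month / 12.0 - float(demo.loc[pid, "birth_year"])
        values = {"age": age, "sex": float(demo.loc[pid, "sex"]),
                  "severity": float(severity[pid])}
        pids.append(pid)
        idxs.append(int(index_month))
        doses.append(exp.doses)
        Zs.append(pseudo_covariates(exp.doses, basis))
        covs.append([values[name] for name in config.covariates])
        drug_months[pid] = drug_rows.to_numpy()
    return _Cohort(
        patient_ids=np.asarray(pids),
        index_months=np.asarray(idxs),
        doses=doses,
        Z=Zs,
        covariate_matrix=np.asarray(covs, dtype=float).reshape(len(pids), -1),
        covariate_names=tuple(config.covariates),
        basis=basis,
        drug_months=drug_months,
    )


def wce_signal_for_code(
    doses_list,
    event_months,
    basis: SplineBasis,
    covariate_matrix=None,
    covariate_names=(),
    Z_list=None,
    B: int = 1000,
    alpha: float = 0.05,
    min_events: int = 10,
    seed=None,
    ties: str = "efron",
):
    """WCE fit + bootstrap test for one code on in-memory exposure data.

    Returns (fit, bootstrap_result, status); fit/bootstrap are None when the
    code cannot be evaluated (too few events or non-convergence).
    """
    ppa = build_arrays(
        doses_list, event_months, basis,
        covariate_matrix=covariate_matrix, covariate_names=covariate_names,
        Z_list=Z_list,
    )
    if ppa.n_events < min_events:
        return None, None, "not evaluated"
    fit = fit_wce_arrays(
        ppa.start, ppa.stop, ppa.event, ppa.X,
        basis=basis, covariate_names=covariate_names, ties=ties,
    )
    if not fit.converged:
        return fit, None, "non-estimable"
    boot = bootstrap_association(ppa, fit, B=B, alpha=alpha, seed=seed)
    return fit, boot, select_signal(boot, alpha)


def _wce_row(cohort: _Cohort, system, code, events_global, config) -> dict:
    idx = cohort.index_months
    pid_pos = {pid: i for i, pid in enumerate(cohort.patient_ids)}
    event_months = np.zeros(cohort.patient_ids.size, dtype=np.int64)
    prevalent = np.zeros(cohort.patient_ids.size, dtype=bool)
    for pid, m in events_global.items():
        if pid not in pid_pos:
            continue
        i = pid_pos[pid]
        rel = int(m) - int(idx[i]) + 1  # 1 = index month
        if rel < 1:
            prevalent[i] = True  # prevalent for this code: excluded
        elif rel <= len(cohort.doses[i]):
            event_months[i] = rel
        # events recorded after the censoring month are treated as censored
    keep = ~prevalent
    doses = [d for d, k in zip(cohort.doses, keep) if k]
    Zs = [z for z, k in zip(cohort.Z, keep) if k]
    evm = event_months[keep]
    n_eval = int(keep.sum() - np.sum(evm == 1))  # index-month events dropped too
    row = {
        "code": code, "code_system": system, "label": code,
        "n_patients_evaluable": n_eval, "method": "WCE",
        "HR": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
    }
    try:
        fit, boot, status = wce_signal_for_code(
            doses, evm, cohort.basis,
            covariate_matrix=cohort.covariate_matrix[keep],
            covariate_names=cohort.covariate_names,
            Z_list=Zs, B=config.bootstraps, alpha=config.alpha,
            min_events=config.min_events,
            seed=code_seed(config.seed, system, code), ties=config.ties,
        )
    except ValueError:
        row.update(n_events=0, status="not evaluated")
        return row
    row["n_events"] = fit.n_events if fit is not None else int(np.sum(evm > 1))
    row["status"] = status
    if boot is not None:
        lo, hi = boot.hr_ci
        row.update(HR=boot.hr, ci_low=lo, ci_high=hi, p=boot.p_value)
    return row


def _cco_rows(cohort: _Cohort, system, code, events_global, config, durations):
    cases = {}
    for pid, m in events_global.items():
        i = np.flatnonzero(cohort.patient_ids == pid)
        if i.size and int(m) > int(cohort.index_months[i[0]]):
            cases[pid] = int(m)
    table = sensitivity_runs(
        cases, cohort.drug_months, code, durations=durations,
        observation_start=0, alpha=config.alpha,
    )
    rows = []
    for _, r in table.iterrows():
        if r["status"] == "ok":
            status = ("significant"
                      if (r["ci_low"] > 1.0 or r["ci_high"] < 1.0)
                      else "not significant")
        elif r["status"] == "no information":
            status = "not evaluated"
        else:
            status = r["status"]
        rows.append({
            "code": code, "code_system": system, "label": code,
            "n_patients_evaluable": int(r["n_sets"]),
            "n_events": int(r["n_cases"]),
            "method": f"CCO-{int(r['duration'])}",
            "HR": r["OR"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
            "p": r["p"], "status": status,
        })
    return rows


def run_screen(
    claims: pd.DataFrame, demographics: pd.DataFrame, config: ScreenConfig
) -> pd.DataFrame:
    """Run the configured methods over every candidate code.

    Returns the signal table (one row per code x method).  Per-code failures
    are logged and reported as non-estimable rows; they never abort the
    screen.  Identical inputs and seed give an identical table.
    """
    if not config.methods:
        return pd.DataFrame(columns=SIGNAL_COLUMNS)
    cohort = materialize_cohort(claims, demographics, config)
    candidates = enumerate_candidates(claims, config.drug_code)
    durations = sorted(
        int(m.split("-")[1]) for m in config.methods if m.startswith("CCO")
    )
    rows = []
    for _, cand in candidates.iterrows():
        system, code = cand["code_system"], cand["code"]
        t0 = time.perf_counter()
        events = ch.first_event_months(claims, system, code).to_dict()
        try:
            if "WCE" in config.methods:
                rows.append(_wce_row(cohort, system, code, events, config))
            if durations:
                rows.extend(
                    _cco_rows(cohort, system, code, events, config, durations)
                )
        except Exception:  # crash isolation: a pathological code never aborts
            log.exception("code %s:%s failed; reported as non-estimable",
                          system, code)
            rows.append({
                "code": code, "code_system": system, "label": code,
                "n_patients_evaluable": 0, "n_events": 0, "method": "WCE",
                "HR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "status": "non-estimable",
            })
        log.debug("code %s:%s screened in %.2fs", system, code,
                  time.perf_counter() - t0)
    table = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    if config.fdr and not table.empty:
        table = add_fdr(table, alpha=config.alpha)
    return table


def add_fdr(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg adjusted p-values per method (optional column)."""
    out = table.copy()
    out["p_fdr"] = np.nan
    for method, grp in out.groupby("method"):
        p = grp["p"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        if not ok.any():
            continue
        m = ok.sum()
        order = np.argsort(p[ok])
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            val = p[ok][order[rank_pos]] * m / (rank_pos + 1)
            prev = min(prev, val)
            adj[order[rank_pos]] = prev
        vals = np.full(p.size, np.nan)
        vals[np.flatnonzero(ok)] = adj
        out.loc[grp.index, "p_fdr"] = vals
    return out


def compare_methods(
    table: pd.DataFrame, method_a: str = "WCE", method_b: str = "CCO-3"
) -> dict:
    """Overlap of significant codes between two methods.

    Returns the significant-code sets (``a_only``, ``b_only``, ``both`` as
    sets of (code_system, code)) and a per-code-system count summary.
    """
    for m in (method_a, method_b):
        if m not in set(table["method"]):
            raise ValueError(f"method {m!r} not present in signal table")

    def sig(method):
        sel = table[(table["method"] == method) & (table["status"] == "significant")]
        return set(zip(sel["code_system"], sel["code"]))

    a, b = sig(method_a), sig(method_b)
    both, a_only, b_only = a & b, a - b, b - a
    systems = sorted(set(table["code_system"]))
    summary = pd.DataFrame(
        [
            {
                "code_system": s,
                f"{method_a}_only": sum(1 for x in a_only if x[0] == s),
                f"{method_b}_only": sum(1 for x in b_only if x[0] == s),
                "both": sum(1 for x in both if x[0] == s),
            }
            for s in systems
        ]
    )
    return {"a_only": a_only, "b_only": b_only, "both": both, "summary": summary}


def forest_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Forest-plot-ready view: code, HR, CI bounds, group (system/method)."""
    est = table[table["status"].isin(["significant", "not significant"])]
    return pd.DataFrame({
        "code": est["code"],
        "HR": est["HR"],
        "ci_low": est["ci_low"],
        "ci_high": est["ci_high"],
        "group": est["code_system"] + "/" + est["method"],
    }).reset_index(drop=True)
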