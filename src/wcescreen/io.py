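"""Delimited-text input/output for claims, demographics and results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import PERSON_PERIOD_COLUMNS, to_month_offset
from .screen import ScreenConfig
from .wce import WceFit

CLAIMS_COLUMNS = ("patient_id", "date", "code_system", "code")


def load_claims(path, origin: str = "2008-01") -> pd.DataFrame:
    """Read a claims CSV (patient_id, date, code_system, code) and attach
    month offsets from the study origin."""
    df = pd.read_csv(path, dtype={"code": str, "code_system": str})
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"claims file {path} missing columns {missing}")
    df["month"] = to_month_offset(df["date"], origin)
    return df


def write_claims(df: pd.DataFrame, path) -> None:
    df.loc[:, list(CLAIMS_COLUMNS)].to_csv(path, index=False)


def load_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "sex", "birth_year") if c not in df.columns]
    if missing:
        raise ValueError(f"demographics file {path} missing columns {missing}")
    return df


def write_person_period(table: pd.DataFrame, path) -> None:
    """Write the counting-process table with the canonical column order
    Id, Start, Stop, Event, then covariates."""
    rest = [c for c in table.columns if c not in PERSON_PERIOD_COLUMNS]
    table[list(PERSON_PERIOD_COLUMNS) + rest].to_csv(path, index=False)


def read_person_period(path) -> pd.DataFrame:
    return pd.read_csv(path)


def fit_summary(fit: WceFit) -> dict:
    """JSON-serializable summary of a WCE fit."""
    return {
        "theta": [float(v) for v in fit.theta],
        "gamma": {n: float(v) for n, v in zip(fit.covariate_names, fit.gamma)},
        "weight": [float(v) for v in fit.weight],
        "window_hr": float(fit.window_hr),
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "n_events": int(fit.n_events),
    }


def write_fit(fit: WceFit, path) -> None:
    Path(path).write_text(json.dumps(fit_summary(fit), indent=2) + "\n")


def load_config(path) -> ScreenConfig:
    """Flat key-value YAML config mirroring the CLI flags."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(ScreenConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("covariates", "severity_codes", "methods"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return ScreenConfig(**raw)


def save_config(config: ScreenConfig, path) -> None:
    d = config.as_dict()
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def write_signal_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    for c in ("HR", "ci_low", "ci_high", "p"):
        if c in out.columns:
            out[c] = np.round(out[c].astype(float), 6)
    out.to_csv(path, index=False)
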