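"""Weighted-cumulative-exposure (WCE) Cox model.

The hazard of the screened health event at month t is

    h(t | history) = h0(t) * exp( sum_v w(v) x(t-v+1) + gamma' C )

where x(u) is the binary drug exposure in month u of follow-up, w(v) is a
cubic-spline weight over lags v = 1..T, and C are baseline covariates (age,
sex, disease severity).  Writing w(v) = sum_k theta_k B_k(v) linearizes the
weighted exposure sum into K artificial "pseudo-covariates"

    Z_k(t) = sum_{u <= t, t-u+1 <= T} B_k(t-u+1) x(u)

so (theta, gamma) is estimated by an ordinary time-dependent Cox partial
likelihood on the person-period table augmented with the Z columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import CoxResult, fit_cox
from .splines import SplineBasis

#: Columns below this many events are not worth fitting; the screen reports
#: such codes as "not evaluated".
MIN_EVENTS_DEFAULT = 10


@dataclass
class WceFit:
    """Fitted WCE model for one event code.

    ``weight[v-1]`` estimates w(v): one dose v months ago multiplies the
    hazard by exp(weight[v-1]).  ``window_hr`` compares continuous exposure
    over the whole T-month window with no exposure: exp(sum_v w(v)).
    """

    theta: np.ndarray
    gamma: np.ndarray
    weight: np.ndarray
    loglik: float
    vcov: np.ndarray
    window_hr: float
    converged: bool
    n_events: int
    basis: SplineBasis = field(repr=False, default=None)
    covariate_names: tuple = ()

    @property
    def log_window_hr(self) -> float:
        return float(np.sum(self.weight))


def pseudo_covariates(doses: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Spline pseudo-covariates Z_k(t) for one exposure series.

    Parameters
    ----------
    doses : sequence of {0,1}, length L
        Monthly exposure indicators x(1..L) from the index month onward.
    basis : SplineBasis

    Returns
    -------
    ndarray, shape (L, K)
        Z[t-1, k] = sum over past dose months u of B_k(t-u+1) x(u), where
        doses more than T months old contribute nothing.

    Notes
    -----
    The lag convention is v = t - u + 1: a dose taken in the current month
    enters through B_k(1).  The sum is a discrete convolution of the dose
    series with each basis column.
    """
    x = np.asarray(doses, dtype=float)
    L = x.size
    out = np.empty((L, basis.k))
    for k in range(basis.k):
        out[:, k] = np.convolve(x, basis.matrix[:, k])[:L]
    return out


def fit_wce(
    table: pd.DataFrame,
    basis: SplineBasis,
    covariates: tuple = (),
    ties: str = "efron",
    min_events: int = MIN_EVENTS_DEFAULT,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
) -> WceFit:
    """Fit the WCE Cox model on a person-period table with Z columns.

    Parameters
    ----------
    table : DataFrame
        Columns ``Id, Start, Stop, Event``, pseudo-covariates ``Z1..ZK``
        matching ``basis``, and the listed covariate columns.
    basis : SplineBasis
        The basis that generated the Z columns.
    covariates : tuple of str
        Baseline covariate column names (e.g. age, sex, severity).
    min_events : int
        Fewer events than this raises ``ValueError`` ("too few events").

    Raises
    ------
    ValueError
        On zero or too few events, or missing columns.
    """
    zcols = [f"Z{k + 1}" for k in range(basis.k)]
    missing = [c for c in zcols + list(covariates) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns in person-period table: {missing}")
    n_events = int(table["Event"].sum())
    if n_events == 0:
        raise ValueError("no events")
    if n_events < min_events:
        raise ValueError(f"too few events ({n_events} < {min_events})")
    X = table[zcols + list(covariates)].to_numpy(dtype=float)
    res = fit_cox(
        table["Start"].to_numpy(),
        table["Stop"].to_numpy(),
        table["Event"].to_numpy(),
        X,
        init=init,
        ties=ties,
        tol=tol,
    )
    return _wrap_fit(res, basis, covariates)


def fit_wce_arrays(
    start,
    stop,
    event,
    Z,
    C=None,
    basis: SplineBasis = None,
    covariate_names: tuple = (),
    ties: str = "efron",
    init: np.ndarray | None = None,
    tol: float = 1e-8,
) -> WceFit:
    """Array-based variant of :func:`fit_wce` (no DataFrame assembly).

    Used on the hot paths (bootstrap replicates, large screens); identical
    likelihood and results.
    """
    X = Z if C is None else np.hstack([Z, C])
    res = fit_cox(start, stop, event, X, init=init, ties=ties, tol=tol)
    return _wrap_fit(res, basis, covariate_names)


def _wrap_fit(res: CoxResult, basis: SplineBasis, covariates) -> WceFit:
    K = basis.k
    theta = res.beta[:K]
    gamma = res.beta[K:]
    weight = basis.matrix @ theta
    try:
        vcov = res.vcov
    except np.linalg.LinAlgError:
        vcov = np.full((res.beta.size, res.beta.size), np.nan)
    return WceFit(
        theta=theta,
        gamma=gamma,
        weight=weight,
        loglik=res.loglik,
        vcov=vcov,
        window_hr=float(np.exp(np.sum(weight))),
        converged=res.converged,
        n_events=res.n_events,
        basis=basis,
        covariate_names=tuple(covariates),
    )


def weight_function(fit: WceFit) -> np.ndarray:
    """Estimated weight function ŵ(1..T) = B @ theta."""
    return fit.basis.matrix @ fit.theta


def window_hr(fit: WceFit) -> float:
    """Hazard ratio for T months of continuous exposure vs none."""
    return float(np.exp(np.sum(weight_function(fit))))
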