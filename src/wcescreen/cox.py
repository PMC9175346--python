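"""Cox proportional-hazards partial likelihood on counting-process data.

Rows are risk intervals (Start, Stop] with time-varying covariates; the event
indicator may be 1 only on a subject's last interval.  Month-granular claims
data produce heavy ties, so the Efron approximation is the default (Breslow
is available).  Estimation is Newton-Raphson with step-halving from a
deterministic start at beta = 0.

When all intervals are unit months (the person-period tables this package
builds), the risk set at event time t is exactly the set of rows with
Stop == t, risk sets are disjoint across event times, and the Efron terms
collapse into grouped sums — the whole score/information evaluation is a
handful of bincounts and two weighted Gram products.  A generic masked path
covers arbitrary interval data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_ABS_BETA = 30.0  # beyond this the likelihood is treated as monotone


@dataclass
class CoxResult:
    beta: np.ndarray
    loglik: float
    loglik_null: float
    gradient: np.ndarray
    information: np.ndarray  # observed information (negative Hessian)
    converged: bool
    n_iter: int
    n_events: int

    @property
    def vcov(self) -> np.ndarray:
        return np.linalg.inv(self.information)


class _UnitIntervalData:
    """Grouped representation for unit-interval person-period rows.

    Only rows whose Stop equals some event time can appear in a risk set,
    so all other rows are dropped up front.  ``g`` maps each kept row to its
    event-time group; deaths are ordered within group so the Efron tie
    fractions l/d can be laid out flat.
    """

    def __init__(self, stop, event, X):
        stop = np.asarray(stop)
        event = np.asarray(event, dtype=bool)
        times = np.unique(stop[event])
        keep = np.isin(stop, times)
        self.X = np.ascontiguousarray(X[keep], dtype=float)
        ev = event[keep]
        g = np.searchsorted(times, stop[keep])
        self.g = g
        self.G = times.size
        self.death = np.flatnonzero(ev)
        self.gd = g[self.death]
        self.Xd = self.X[self.death]
        d_t = np.bincount(self.gd, minlength=self.G).astype(float)  # ties per time
        self.d_t = d_t
        # flat (t, l) layout: one entry per death, fractions l/d_t
        reps = d_t.astype(int)
        self.flat_g = np.repeat(np.arange(self.G), reps)
        offs = np.concatenate([[0], np.cumsum(reps)[:-1]])
        self.flat_f = (np.arange(reps.sum()) - np.repeat(offs, reps)) / np.repeat(
            d_t, reps
        )
        self.p = self.X.shape[1]
        self.n_events = int(ev.sum())

    def _sums(self, phi):
        s0 = np.bincount(self.g, weights=phi, minlength=self.G)
        d0 = np.bincount(self.gd, weights=phi[self.death], minlength=self.G)
        return s0, d0

    def loglik(self, beta, ties):
        eta = self.X @ beta
        if eta.size and np.max(np.abs(eta)) > 300.0:  # exp would overflow
            return -np.inf
        phi = np.exp(eta)
        s0, d0 = self._sums(phi)
        f = self.flat_f if ties == "efron" else np.zeros_like(self.flat_f)
        denom = s0[self.flat_g] - f * d0[self.flat_g]
        return float(eta[self.death].sum() - np.log(denom).sum())

    def full(self, beta, ties):
        """(loglik, gradient, observed information)."""
        eta = self.X @ beta
        if eta.size and np.max(np.abs(eta)) > 300.0:
            return -np.inf, None, None
        phi = np.exp(eta)
        G, p = self.G, self.p
        s0, d0 = self._sums(phi)
        phid = phi[self.death]
        s1 = np.empty((G, p))
        d1 = np.empty((G, p))
        for j in range(p):
            s1[:, j] = np.bincount(self.g, weights=phi * self.X[:, j], minlength=G)
            d1[:, j] = np.bincount(
                self.gd, weights=phid * self.Xd[:, j], minlength=G
            )
        f = self.flat_f if ties == "efron" else np.zeros_like(self.flat_f)
        fg = self.flat_g
        denom = s0[fg] - f * d0[fg]
        inv = 1.0 / denom
        ll = float(eta[self.death].sum() - np.log(denom).sum())
        A = np.bincount(fg, weights=inv, minlength=G)
        Bc = np.bincount(fg, weights=f * inv, minlength=G)
        A2 = np.bincount(fg, weights=inv * inv, minlength=G)
        AB = np.bincount(fg, weights=f * inv * inv, minlength=G)
        B2 = np.bincount(fg, weights=f * f * inv * inv, minlength=G)
        grad = self.Xd.sum(axis=0) - (A @ s1 - Bc @ d1)
        wr = phi * A[self.g]
        wd = phid * Bc[self.gd]
        info = (self.X * wr[:, None]).T @ self.X - (self.Xd * wd[:, None]).T @ self.Xd
        info -= np.einsum("g,gi,gj->ij", A2, s1, s1)
        info += np.einsum("g,gi,gj->ij", AB, s1, d1)
        info += np.einsum("g,gi,gj->ij", AB, d1, s1)
        info -= np.einsum("g,gi,gj->ij", B2, d1, d1)
        return ll, grad, info


class _GenericData:
    """Masked risk sets for arbitrary (Start, Stop] interval data."""

    def __init__(self, start, stop, event, X):
        start = np.asarray(start, dtype=float)
        stop = np.asarray(stop, dtype=float)
        event = np.asarray(event, dtype=bool)
        self.X = np.ascontiguousarray(X, dtype=float)
        self.groups = []
        for t in np.unique(stop[event]):
            risk = np.flatnonzero((start < t) & (t <= stop))
            death = risk[event[risk]]
            self.groups.append((risk, death))
        self.p = self.X.shape[1]
        self.n_events = int(event.sum())
        self.death = np.flatnonzero(event)

    def loglik(self, beta, ties):
        eta = self.X @ beta
        if eta.size and np.max(np.abs(eta)) > 300.0:
            return -np.inf
        phi = np.exp(eta)
        ll = 0.0
        for risk, death in self.groups:
            d = death.size
            s0 = phi[risk].sum()
            d0 = phi[death].sum()
            ll += float(eta[death].sum())
            fracs = np.zeros(d) if ties == "breslow" else np.arange(d) / d
            ll -= float(np.log(s0 - fracs * d0).sum())
        return ll

    def full(self, beta, ties):
        eta = self.X @ beta
        if eta.size and np.max(np.abs(eta)) > 300.0:
            return -np.inf, None, None
        phi = np.exp(eta)
        ll = 0.0
        grad = np.zeros(self.p)
        info = np.zeros((self.p, self.p))
        for risk, death in self.groups:
            d = death.size
            Xr, phir = self.X[risk], phi[risk]
            Xd, phid = self.X[death], phi[death]
            s0, s1 = phir.sum(), phir @ Xr
            s2 = (Xr * phir[:, None]).T @ Xr
            d0, d1 = phid.sum(), phid @ Xd
            d2 = (Xd * phid[:, None]).T @ Xd
            ll += float(eta[death].sum())
            grad += Xd.sum(axis=0)
            fracs = np.zeros(d) if ties == "breslow" else np.arange(d) / d
            for f in fracs:
                denom = s0 - f * d0
                u = (s1 - f * d1) / denom
                ll -= np.log(denom)
                grad -= u
                info += (s2 - f * d2) / denom - np.outer(u, u)
        return ll, grad, info


def _make_data(start, stop, event, X):
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    if np.allclose(stop - start, 1.0):
        return _UnitIntervalData(stop, event, X)
    return _GenericData(start, stop, event, X)


def fit_cox(
    start,
    stop,
    event,
    X,
    init: np.ndarray | None = None,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Maximize the Cox partial likelihood on counting-process rows.

    Parameters
    ----------
    start, stop : array-like
        Interval bounds; intervals are closed on the right.
    event : array-like of {0,1}
        Terminal event indicator per row.
    X : ndarray (n_rows, p)
        Covariate values over each interval.
    init : ndarray, optional
        Warm start (used by the bootstrap); defaults to zeros.
    ties : {"efron", "breslow"}
    tol : float
        Convergence on the max-norm of the score.

    Raises
    ------
    ValueError
        If the table contains no events.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    data = _make_data(start, stop, event, X)
    if data.n_events == 0:
        raise ValueError("no events in table")
    p = data.p
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    ll, grad, info = data.full(beta, ties)
    if grad is None:  # degenerate warm start: restart from zero
        beta = np.zeros(p)
        ll, grad, info = data.full(beta, ties)
    ll_null = ll if init is None else data.loglik(np.zeros(p), ties)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        factor = 1.0
        for _ in range(30):  # step-halving until the likelihood does not drop
            cand = beta + factor * step
            ll_new = data.loglik(cand, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            break
        beta = cand
        ll, grad, info = data.full(beta, ties)
        if not np.isfinite(ll) or np.max(np.abs(beta)) > _MAX_ABS_BETA:
            break
    if np.isfinite(ll) and np.max(np.abs(beta)) <= _MAX_ABS_BETA:
        converged = bool(np.max(np.abs(grad)) < tol)
    else:
        converged = False
    return CoxResult(
        beta=beta,
        loglik=float(ll),
        loglik_null=float(ll_null),
        gradient=grad,
        information=info,
        converged=converged,
        n_iter=n_iter,
        n_events=data.n_events,
    )
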