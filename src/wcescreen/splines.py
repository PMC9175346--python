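"""Cubic B-spline bases over exposure lags.

The weight function w(v) gives the log-hazard contribution of one dose taken
v months before the current interval, for lags v = 1..T (T is the exposure
window).  It is modelled as a cubic regression spline, so w(v) = B(v) @ theta
where B is the basis matrix built here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasis:
    """Cubic B-spline basis evaluated at integer lags 1..window.

    Attributes
    ----------
    window : int
        Length T of the exposure window in months.
    nknots : int
        Number of interior knots (equally spaced over [1, T]).
    constrained : str
        ``"none"`` for the full basis (K = nknots + 4) or ``"right"`` to
        force the weight function to vanish smoothly at lag T by dropping
        the last two basis functions (K = nknots + 2).
    matrix : ndarray, shape (window, K)
        Basis values B_k(v) at v = 1..window.
    knots : ndarray
        Full (augmented) knot vector.
    """

    window: int
    nknots: int
    constrained: str = "none"
    degree: int = 3
    matrix: np.ndarray = field(repr=False, default=None)
    knots: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        """Number of basis columns."""
        return self.matrix.shape[1]

    def evaluate(self, lags: np.ndarray) -> np.ndarray:
        """Evaluate the basis at arbitrary (possibly non-integer) lags."""
        lags = np.asarray(lags, dtype=float)
        full = BSpline.design_matrix(
            np.clip(lags, 1.0, float(self.window)), self.knots, self.degree
        ).toarray()
        if self.constrained == "right":
            full = full[:, :-2]
        return full


def make_basis(window: int, nknots: int = 1, constrained: str = "none") -> SplineBasis:
    """Build the cubic spline basis for the exposure weight function.

    Parameters
    ----------
    window : int
        Exposure window T in months; doses older than T months contribute
        nothing to the hazard.
    nknots : int
        Interior knots, equally spaced over [1, T].
    constrained : {"none", "right"}
        Whether to constrain the weight function to zero at the far end of
        the window.

    Returns
    -------
    SplineBasis
        With ``matrix`` of shape (T, K), K = nknots + 4 (unconstrained) or
        nknots + 2 (right-constrained).
    """
    if constrained not in ("none", "right"):
        raise ValueError(f"constrained must be 'none' or 'right', got {constrained!r}")
    if nknots < 0:
        raise ValueError("nknots must be >= 0")
    if window < nknots + 5:
        raise ValueError(
            f"window T={window} too small to identify a cubic spline with "
            f"{nknots} interior knots (need T >= nknots + 5)"
        )
    degree = 3
    interior = np.linspace(1.0, float(window), nknots + 2)[1:-1]
    knots = np.concatenate(
        [np.repeat(1.0, degree + 1), interior, np.repeat(float(window), degree + 1)]
    )
    lags = np.arange(1, window + 1, dtype=float)
    mat = BSpline.design_matrix(lags, knots, degree).toarray()
    if constrained == "right":
        mat = mat[:, :-2]
    basis = SplineBasis(
        window=window, nknots=nknots, constrained=constrained, degree=degree
    )
    object.__setattr__(basis, "matrix", mat)
    object.__setattr__(basis, "knots", knots)
    return basis
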