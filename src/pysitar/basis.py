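"""Natural cubic regression spline basis.

The SITAR mean curve h(.) is a natural cubic regression spline: cubic
between knots, linear beyond the boundary knots.  The basis is the
truncated-power construction with ``df`` columns (excluding the
intercept): with knots xi_1 < ... < xi_K (boundary knots included,
K = df + 1),

    N_1(x) = x,
    N_{k+1}(x) = d_k(x) - d_{K-1}(x),   k = 1, ..., K - 2,
    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k).

Interior knots sit at equally spaced quantiles of the observed ages;
boundary knots at the min/max.  Linear extrapolation outside the
boundary knots is automatic in this parameterization, which matters in
SITAR because the subject-shifted, time-scaled ages routinely fall a
little outside the observed age range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineModel", "build_spline_basis", "DegenerateDesignError"]


class DegenerateDesignError(ValueError):
    """Raised when there are too few distinct x values for the requested df."""


@dataclass
class SplineModel:
    """A natural cubic regression spline: knots plus (optional) coefficients.

    Parameters
    ----------
    knots : ndarray
        All knots, strictly increasing; first and last are the boundary
        knots, the rest interior.
    coef : ndarray or None
        Basis coefficients, length ``df``.  ``None`` until fitted.
    intercept : float
        Constant term.
    """

    knots: np.ndarray
    coef: np.ndarray | None = None
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.size < 3:
            raise ValueError("need at least 3 knots (df >= 2)")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.coef is not None:
            self.coef = np.asarray(self.coef, dtype=float)
            if self.coef.size != self.df:
                raise ValueError(
                    f"coef length {self.coef.size} != df {self.df}"
                )

    @property
    def df(self) -> int:
        """Number of basis columns (excluding the intercept)."""
        return self.knots.size - 1

    @property
    def boundary_knots(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    @property
    def interior_knots(self) -> np.ndarray:
        return self.knots[1:-1]

    # -- basis evaluation -------------------------------------------------

    def design(self, x: np.ndarray) -> np.ndarray:
        """Design matrix, shape (len(x), df).  No intercept column."""
        x = np.asarray(x, dtype=float)
        xi = self.knots
        K = xi.size
        P = np.maximum(x[:, None] - xi[None, :], 0.0) ** 3  # (n, K)
        d = (P[:, : K - 1] - P[:, K - 1 : K]) / (xi[K - 1] - xi[: K - 1])
        out = np.empty((x.size, K - 1))
        out[:, 0] = x
        out[:, 1:] = d[:, : K - 2] - d[:, K - 2 : K - 1]
        return out

    def design_deriv(self, x: np.ndarray) -> np.ndarray:
        """First derivative of each basis column at x, shape (len(x), df)."""
        x = np.asarray(x, dtype=float)
        xi = self.knots
        K = xi.size
        P = 3.0 * np.maximum(x[:, None] - xi[None, :], 0.0) ** 2
        d = (P[:, : K - 1] - P[:, K - 1 : K]) / (xi[K - 1] - xi[: K - 1])
        out = np.empty((x.size, K - 1))
        out[:, 0] = 1.0
        out[:, 1:] = d[:, : K - 2] - d[:, K - 2 : K - 1]
        return out

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the fitted spline (intercept + basis @ coef)."""
        self._require_coef()
        return self.intercept + self.design(x) @ self.coef

    def deriv(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the fitted spline's first derivative."""
        self._require_coef()
        return self.design_deriv(x) @ self.coef

    def _require_coef(self) -> None:
        if self.coef is None:
            raise ValueError("spline has no coefficients; fit it first")


def build_spline_basis(x_values: np.ndarray, df: int) -> SplineModel:
    """Place knots for a natural cubic spline with ``df`` basis columns.

    Boundary knots at min/max of ``x_values``; the ``df - 1`` interior
    knots at equally spaced quantiles (i/df for i = 1..df-1).

    Raises
    ------
    DegenerateDesignError
        If there are fewer than ``df + 2`` distinct x values.
    """
    if df < 2:
        raise ValueError("df must be >= 2")
    x = np.asarray(x_values, dtype=float)
    distinct = np.unique(x)
    if distinct.size < df + 2:
        raise DegenerateDesignError(
            f"need at least {df + 2} distinct x values for df={df}, "
            f"got {distinct.size}"
        )
    probs = np.arange(1, df) / df
    interior = np.quantile(x, probs)
    knots = np.concatenate([[distinct[0]], np.atleast_1d(interior), [distinct[-1]]])
    if np.any(np.diff(knots) <= 0):
        raise DegenerateDesignError(
            "tied quantile knots: x values too concentrated for requested df"
        )
    return SplineModel(knots=knots)
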