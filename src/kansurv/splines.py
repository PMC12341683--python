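"""Uniform B-spline bases and learnable spline curves on a bounded grid.

A :class:`Spline` is a degree-``k`` B-spline curve on ``G`` uniform grid
intervals spanning ``[lo, hi]``, with the knot vector extended by ``k``
uniformly spaced knots on each side.  It therefore carries ``G + k`` basis
functions and the same number of trainable coefficients, and evaluates as

    spline(x) = sum_i  c_i * B_{i,k}(x).

The basis is treated as supported on the grid domain ``[lo, hi]``: basis
values are zero outside it, and callers that need extrapolation clamp their
inputs to the domain boundary first (see ``network.ActivationEdge``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import ConfigurationError

__all__ = ["Spline", "bspline_basis", "fit_spline_to_samples"]


def _uniform_knots(degree: int, grid_intervals: int, lo: float, hi: float) -> np.ndarray:
    h = (hi - lo) / grid_intervals
    return lo + h * np.arange(-degree, grid_intervals + degree + 1, dtype=float)


@dataclass
class Spline:
    """A univariate B-spline curve with trainable coefficients.

    Parameters
    ----------
    degree : int
        Polynomial degree ``k`` of the basis (3 for cubic splines).
    grid_intervals : int
        Number of grid intervals ``G`` on the base domain.
    lo, hi : float
        Base domain of the grid.
    coef : ndarray of shape (G + k,), optional
        Basis coefficients; zeros if omitted.
    """

    degree: int = 3
    grid_intervals: int = 5
    lo: float = -1.0
    hi: float = 1.0
    coef: np.ndarray | None = None
    knots: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.degree < 1 or self.grid_intervals < 1:
            raise ConfigurationError(
                f"degree and grid_intervals must be positive, got "
                f"k={self.degree}, G={self.grid_intervals}"
            )
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.hi > self.lo):
            raise ConfigurationError(f"invalid grid domain [{self.lo}, {self.hi}]")
        self.knots = _uniform_knots(self.degree, self.grid_intervals, self.lo, self.hi)
        if self.coef is None:
            self.coef = np.zeros(self.n_basis)
        else:
            self.coef = np.asarray(self.coef, dtype=float)
            if self.coef.shape != (self.n_basis,):
                raise ConfigurationError(
                    f"expected {self.n_basis} coefficients (G + k), got {self.coef.shape}"
                )

    @property
    def n_basis(self) -> int:
        return self.grid_intervals + self.degree

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Basis values ``B_{i,k}(x)`` as a dense ``(n, G + k)`` array.

        Values are zero for ``x`` outside ``[lo, hi]``.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros((x.size, self.n_basis))
        inside = (x >= self.lo) & (x <= self.hi)
        if inside.any():
            out[inside] = BSpline.design_matrix(
                x[inside], self.knots, self.degree
            ).toarray()
        return out

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.design_matrix(x) @ self.coef

    def derivative_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients and knots of the degree ``k - 1`` derivative spline."""
        k, t, c = self.degree, self.knots, self.coef
        denom = t[k + 1 : k + c.size] - t[1:c.size]
        dcoef = k * np.diff(c) / denom
        return dcoef, t[1:-1]

    def derivative(self, x: np.ndarray) -> np.ndarray:
        """d spline / dx, zero outside the grid domain."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        dcoef, subknots = self.derivative_coefficients()
        out = np.zeros(x.size)
        inside = (x >= self.lo) & (x <= self.hi)
        if inside.any():
            D = BSpline.design_matrix(x[inside], subknots, self.degree - 1).toarray()
            out[inside] = D @ dcoef
        return out

    def copy(self) -> "Spline":
        return Spline(
            degree=self.degree,
            grid_intervals=self.grid_intervals,
            lo=self.lo,
            hi=self.hi,
            coef=self.coef.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "grid_intervals": self.grid_intervals,
            "lo": self.lo,
            "hi": self.hi,
            "coef": self.coef.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Spline":
        return cls(
            degree=d["degree"],
            grid_intervals=d["grid_intervals"],
            lo=d["lo"],
            hi=d["hi"],
            coef=np.asarray(d["coef"], dtype=float),
        )


def bspline_basis(x, spline: Spline) -> np.ndarray:
    """All basis values ``B_{i,k}(x)``, ``i = 0 .. G + k - 1``.

    For scalar ``x`` returns a vector of length ``G + k``; for array input
    returns shape ``(n, G + k)``.  Values are non-negative everywhere, sum
    to one strictly inside the grid domain, and vanish outside it.
    """
    scalar = np.isscalar(x) or np.ndim(x) == 0
    B = spline.design_matrix(x)
    return B[0] if scalar else B


def fit_spline_to_samples(
    x: np.ndarray,
    y: np.ndarray,
    degree: int = 3,
    grid_intervals: int = 5,
    lo: float = -1.0,
    hi: float = 1.0,
) -> Spline:
    """Least-squares fit of a spline curve to sample pairs ``(x, y)``."""
    sp = Spline(degree=degree, grid_intervals=grid_intervals, lo=lo, hi=hi)
    B = sp.design_matrix(np.asarray(x, dtype=float))
    coef, *_ = np.linalg.lstsq(B, np.asarray(y, dtype=float), rcond=None)
    sp.coef = coef
    return sp
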