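"""Natural cubic spline bases and curves with analytic derivatives.

The SITAR mean curve g(t) is a natural cubic spline: piecewise cubic,
twice continuously differentiable, with zero second derivative at (and
linear extrapolation beyond) the boundary knots.  The basis here follows
the R ``splines::ns`` convention: ``df`` basis columns spanning, together
with a separate intercept, the space of natural cubic splines with
``df - 1`` interior knots.

Construction: cubic B-splines on the full knot vector are projected onto
the null space of the constraints {second derivative zero at both
boundary knots, coefficient vector orthogonal to the constant function}.
Evaluation outside the boundary knots extends each function linearly
(continuous value and first derivative, zero curvature), which is the
defining natural-tail behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["NaturalSplineBasis", "NaturalSplineCurve", "build_natural_spline_basis"]


def _full_knot_vector(interior: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


@dataclass(frozen=True)
class NaturalSplineBasis:
    """Natural cubic spline basis on a fixed knot set.

    Attributes
    ----------
    interior_knots : array of float
        Strictly increasing knots strictly inside ``(lo, hi)``.
    boundary_knots : (lo, hi)
        Outside this interval every basis function is linear.
    df : int
        Number of basis columns (intercept not included).
    """

    interior_knots: np.ndarray
    boundary_knots: tuple[float, float]
    _Z: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        lo, hi = self.boundary_knots
        interior = np.asarray(self.interior_knots, dtype=float)
        if not np.all(np.diff(np.concatenate([[lo], interior, [hi]])) > 0):
            raise ValueError("knots must be strictly increasing inside the boundary")
        object.__setattr__(self, "interior_knots", interior)
        if self._Z is None:
            object.__setattr__(self, "_Z", self._constraint_null_space())

    # -- construction -------------------------------------------------
    def _constraint_null_space(self) -> np.ndarray:
        t = self.knot_vector
        nb = len(t) - 4  # number of cubic B-splines
        lo, hi = self.boundary_knots
        d2 = np.zeros((2, nb))
        for j in range(nb):
            coef = np.zeros(nb)
            coef[j] = 1.0
            sp2 = BSpline(t, coef, 3).derivative(2)
            d2[0, j] = sp2(lo)
            d2[1, j] = sp2(hi)
        # The all-ones coefficient vector is the constant function; excluding
        # it keeps the design [1, N] full rank.
        constraints = np.vstack([d2, np.ones(nb)])
        Z = null_space(constraints)
        return Z

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return _full_knot_vector(self.interior_knots, lo, hi)

    @property
    def df(self) -> int:
        return self._Z.shape[1]

    # -- evaluation ---------------------------------------------------
    def design(self, x, nu: int = 0) -> np.ndarray:
        """Basis (or derivative) matrix, shape (len(x), df).

        ``nu`` is the derivative order (0, 1 or 2).  Outside the boundary
        knots the value extends linearly: the first derivative is frozen
        at its boundary value and the second derivative is zero.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.boundary_knots
        t = self.knot_vector
        nb = self._Z.shape[0]
        out = np.empty((x.size, self.df))

        inside = (x >= lo) & (x <= hi)

        def bmat(pts, order):
            if order == 0:
                return BSpline.design_matrix(pts, t, 3).toarray()
            cols = np.empty((pts.size, nb))
            for j in range(nb):
                coef = np.zeros(nb)
                coef[j] = 1.0
                cols[:, j] = BSpline(t, coef, 3).derivative(order)(pts)
            return cols

        if inside.any():
            out[inside] = bmat(x[inside], nu) @ self._Z
        for bound, mask in ((lo, x < lo), (hi, x > hi)):
            if not mask.any():
                continue
            pt = np.array([bound])
            v0 = (bmat(pt, 0) @ self._Z)[0]
            v1 = (bmat(pt, 1) @ self._Z)[0]
            if nu == 0:
                out[mask] = v0 + np.outer(x[mask] - bound, v1)
            elif nu == 1:
                out[mask] = v1
            else:
                out[mask] = 0.0
        return out

    def curve(self, coef, intercept: float = 0.0) -> "NaturalSplineCurve":
        return NaturalSplineCurve(self, np.asarray(coef, dtype=float), float(intercept))


class NaturalSplineCurve:
    """A fitted natural cubic spline g(x) = intercept + N(x) @ coef.

    Exposes analytic value, slope and curvature; linear outside the
    boundary knots.
    """

    def __init__(self, basis: NaturalSplineBasis, coef: np.ndarray, intercept: float = 0.0):
        if len(coef) != basis.df:
            raise ValueError(f"expected {basis.df} coefficients, got {len(coef)}")
        self.basis = basis
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)
        t = basis.knot_vector
        self._sp = BSpline(t, basis._Z @ self.coef, 3)
        self._sp1 = self._sp.derivative(1)
        self._sp2 = self._sp.derivative(2)
        lo, hi = basis.boundary_knots
        self._lo, self._hi = lo, hi
        self._v_lo, self._v_hi = float(self._sp(lo)), float(self._sp(hi))
        self._s_lo, self._s_hi = float(self._sp1(lo)), float(self._sp1(hi))

    def value(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.empty_like(x)
        inside = (x >= self._lo) & (x <= self._hi)
        out[inside] = self._sp(x[inside])
        below = x < self._lo
        above = x > self._hi
        out[below] = self._v_lo + self._s_lo * (x[below] - self._lo)
        out[above] = self._v_hi + self._s_hi * (x[above] - self._hi)
        out += self.intercept
        return out[0] if scalar else out

    def slope(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.empty_like(x)
        inside = (x >= self._lo) & (x <= self._hi)
        out[inside] = self._sp1(x[inside])
        out[x < self._lo] = self._s_lo
        out[x > self._hi] = self._s_hi
        return out[0] if scalar else out

    def curvature(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.zeros_like(x)
        inside = (x >= self._lo) & (x <= self._hi)
        out[inside] = self._sp2(x[inside])
        return out[0] if scalar else out

    __call__ = value


def build_natural_spline_basis(ages, df: int) -> NaturalSplineBasis:
    """Basis with ``df - 1`` interior knots at equally spaced quantiles of ``ages``.

    Boundary knots sit at the age range limits.  ``df`` must be at least 2
    and leave at least one distinct age per knot.
    """
    ages = np.asarray(ages, dtype=float)
    if df < 2:
        raise ValueError("df must be >= 2")
    distinct = np.unique(ages)
    if distinct.size <= df:
        raise ValueError(f"df={df} requires more than {df} distinct ages (got {distinct.size})")
    lo, hi = float(distinct.min()), float(distinct.max())
    if hi - lo <= 0:
        raise ValueError("ages must span a positive range")
    k = df - 1
    probs = np.arange(1, k + 1) / (k + 1)
    interior = np.quantile(ages, probs)
    if np.any(np.diff(interior) <= 0) or interior[0] <= lo or interior[-1] >= hi:
        # Heavily tied ages: fall back to equally spaced knots.
        interior = np.linspace(lo, hi, k + 2)[1:-1]
    return NaturalSplineBasis(interior_knots=interior, boundary_knots=(lo, hi))
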