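"""Natural cubic regression splines on fixed knots.

The basis is the *cardinal* one: basis function j is the natural cubic
interpolant of the j-th unit vector on the knots, so a curve's coefficient
vector is exactly its values at the knots.  That makes serialization
lossless: storing (knots, values) reconstructs the identical function.
Beyond the boundary knots the curve is continued linearly (value plus
boundary slope), which keeps extrapolated reference curves tame.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["SplineCurve", "natural_cubic_design", "constrained_design", "knots_from_quantiles"]


def _natural_interpolants(knots: np.ndarray) -> list[CubicSpline]:
    eye = np.eye(len(knots))
    return [CubicSpline(knots, eye[:, j], bc_type="natural") for j in range(len(knots))]


def _eval_with_linear_tails(spl: CubicSpline, knots: np.ndarray, x: np.ndarray) -> np.ndarray:
    lo, hi = knots[0], knots[-1]
    x = np.asarray(x, float)
    out = spl(np.clip(x, lo, hi))
    below, above = x < lo, x > hi
    if np.any(below):
        out = np.where(below, spl(lo) + spl(lo, 1) * (x - lo), out)
    if np.any(above):
        out = np.where(above, spl(hi) + spl(hi, 1) * (x - hi), out)
    return out


def natural_cubic_design(x, knots) -> np.ndarray:
    """Design matrix of the cardinal natural cubic basis (one column per knot)."""
    knots = np.asarray(knots, float)
    x = np.atleast_1d(np.asarray(x, float))
    cols = [
        _eval_with_linear_tails(spl, knots, x) for spl in _natural_interpolants(knots)
    ]
    return np.column_stack(cols)


def sum_zero_contrast(q: int) -> np.ndarray:
    """Orthonormal (q, q-1) basis of the subspace of knot-values summing to zero.

    Reparameterising spline coefficients as v = Z @ gamma removes the
    constant direction, so the spline never competes with the intercept.
    """
    ones = np.ones((q, 1)) / np.sqrt(q)
    # Householder-style completion of the orthonormal basis.
    full = np.linalg.qr(np.hstack([ones, np.eye(q)[:, : q - 1]]))[0]
    return full[:, 1:q]


def constrained_design(x, knots) -> np.ndarray:
    """Design for the sum-to-zero constrained basis: df = len(knots) - 1 columns."""
    B = natural_cubic_design(x, knots)
    return B @ sum_zero_contrast(len(np.asarray(knots)))


def knots_from_quantiles(values, df: int) -> np.ndarray:
    """df+1 knots at evenly spaced quantiles (including min and max) of `values`.

    Duplicate quantiles are collapsed; the returned knot count may then be
    smaller, reducing the effective df.
    """
    if df < 1:
        raise ValueError("df must be >= 1 to build a spline basis")
    qs = np.linspace(0.0, 1.0, df + 1)
    knots = np.unique(np.quantile(np.asarray(values, float), qs))
    if len(knots) < 2:
        raise ValueError("need at least 2 distinct knots; data too degenerate")
    return knots


class SplineCurve:
    """A natural cubic spline stored as (knots, values at knots).

    Evaluation uses the natural interpolant inside the knot span and linear
    continuation outside it, matching the regression basis used in fitting.
    """

    def __init__(self, knots, values):
        self.knots = np.asarray(knots, float)
        self.values = np.asarray(values, float)
        if self.knots.shape != self.values.shape or self.knots.ndim != 1:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self._spl = CubicSpline(self.knots, self.values, bc_type="natural")

    def __call__(self, x):
        out = _eval_with_linear_tails(self._spl, self.knots, np.atleast_1d(x))
        return out if np.ndim(x) else float(out[0])

    def to_dict(self) -> dict:
        return {"knots": self.knots.tolist(), "values": self.values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineCurve":
        return cls(d["knots"], d["values"])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SplineCurve)
            and self.knots.shape == other.knots.shape
            and np.allclose(self.knots, other.knots)
            and np.allclose(self.values, other.values)
        )
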