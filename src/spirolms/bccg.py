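"""Box-Cox Cole-Green (BCCG) distribution.

The BCCG distribution underlies the LMS method for reference centiles:
a positive measurand ``y`` with median ``M``, coefficient of variation
``S`` and Box-Cox skewness power ``L`` is modelled so that

    z = ((y/M)**L - 1) / (L*S)        (L != 0)
    z = ln(y/M) / S                   (L == 0, the lognormal limit)

is a standard normal deviate.  All functions here follow the usual
Cole-Green convention of ignoring the truncation mass below y = 0
(the point mass Phi(-1/(L*S)) for L > 0), which is negligible for the
small S*|L| typical of spirometry; :func:`truncation_mass` reports it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LMSPoint",
    "z_exact",
    "y_from_z",
    "cdf",
    "pdf",
    "quantile",
    "sample",
    "truncation_mass",
]

#: |L| below which the lognormal (L -> 0) branch is used.
L_ZERO_TOL = 1e-6


@dataclass(frozen=True)
class LMSPoint:
    """One point on the L, M, S curves.

    M : median, in measurand units (> 0)
    S : coefficient of variation (> 0)
    L : Box-Cox power (L = 0 gives the lognormal limit)
    """

    M: float
    S: float
    L: float

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.M) > 0):
            raise ValueError(f"M must be positive, got {self.M}")
        if not np.all(np.asarray(self.S) > 0):
            raise ValueError(f"S must be positive, got {self.S}")


def _unpack(p: LMSPoint | tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(p, LMSPoint):
        M, S, L = p.M, p.S, p.L
    else:
        M, S, L = p
    return np.asarray(M, float), np.asarray(S, float), np.asarray(L, float)


def z_exact(y, p: LMSPoint | tuple):
    """Exact BCCG z-transform of a positive measurand.

    Continuous in L at 0: uses ``expm1(L*ln(y/M))/(L*S)``, switching to the
    analytic lognormal limit ``ln(y/M)/S`` for |L| < 1e-6.
    """
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValueError("y must be positive for the BCCG z-transform")
    M, S, L = _unpack(p)
    w = np.log(y / M)
    small = np.abs(L) < L_ZERO_TOL
    # np.where evaluates both branches; guard the division.
    L_safe = np.where(small, 1.0, L)
    z = np.where(small, w / S, np.expm1(L_safe * w) / (L_safe * S))
    return z if z.shape else float(z)


def y_from_z(z, p: LMSPoint | tuple):
    """Inverse of :func:`z_exact`: the measurand at standard-normal deviate z."""
    z = np.asarray(z, float)
    M, S, L = _unpack(p)
    small = np.abs(L) < L_ZERO_TOL
    L_safe = np.where(small, 1.0, L)
    arg = 1.0 + L_safe * S * z
    if np.any(~small & (arg <= 0)):
        bound = -1.0 / (L_safe * S)
        raise ValueError(
            "quantile outside the BCCG support: 1 + L*S*z <= 0 "
            f"(truncation bound z = {np.min(bound):.4g})"
        )
    y = np.where(small, M * np.exp(S * z), M * np.power(np.where(arg > 0, arg, 1.0), 1.0 / L_safe))
    return y if y.shape else float(y)


def cdf(y, p: LMSPoint | tuple):
    """P(Y <= y) = Phi(z_exact(y)), ignoring the truncation mass."""
    return stats.norm.cdf(z_exact(y, p))


def pdf(y, p: LMSPoint | tuple):
    """BCCG density phi(z) * y^(L-1) / (M^L * S) (unnormalised for truncation)."""
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValueError("y must be positive")
    M, S, L = _unpack(p)
    z = z_exact(y, p)
    # dz/dy = y^(L-1) / (M^L * S); at L=0 this is 1/(y*S).
    log_jac = (L - 1.0) * np.log(y) - L * np.log(M) - np.log(S)
    d = np.exp(stats.norm.logpdf(z) + log_jac)
    return d if d.shape else float(d)


def quantile(prob, p: LMSPoint | tuple):
    """Quantile function: M*(1 + L*S*Phi^-1(prob))^(1/L), lognormal limit at L=0."""
    prob = np.asarray(prob, float)
    if np.any((prob <= 0) | (prob >= 1)):
        raise ValueError("prob must lie strictly in (0, 1)")
    return y_from_z(stats.norm.ppf(prob), p)


def sample(n: int, p: LMSPoint | tuple, seed: int | np.random.Generator):
    """Draw n values: y = M*(1+L*S*Z)^(1/L) with Z ~ N(0,1).

    Draws falling outside the support (1 + L*S*Z <= 0) are redrawn; for
    spirometry-scale S*|L| this happens with probability < 1e-6.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M, S, L = _unpack(p)
    z = rng.standard_normal(n)
    small = np.abs(L) < L_ZERO_TOL
    L_safe = np.where(small, 1.0, L)
    for _ in range(100):
        bad = ~small & (1.0 + L_safe * S * z <= 0)
        if not np.any(bad):
            break
        z[bad] = rng.standard_normal(int(np.sum(bad)))
    return np.asarray(y_from_z(z, p))


def truncation_mass(p: LMSPoint | tuple):
    """Probability mass outside the support: Phi(-1/(|L|*S)) for L != 0, 0 at L = 0.

    For L > 0 this is the mass below y = 0; for L < 0 the mass above the
    finite upper z-bound.  Both reduce to the same expression.
    """
    M, S, L = _unpack(p)
    absL = np.abs(L)
    mass = np.where(absL > L_ZERO_TOL, stats.norm.cdf(-1.0 / np.where(absL > 0, absL, 1.0) / S), 0.0)
    return mass if mass.shape else float(mass)
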