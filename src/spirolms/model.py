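"""Shared representation of an LMS reference model for one (index, sex).

Both the synthetic ground-truth models and fitted models evaluate to the
same structure, so prediction, lookup tables and cohort comparisons treat
them identically:

    ln M = a + b*ln(height_cm) + c*ln(age_y) + mu_spline(age)
    ln S = s0 + s1*ln(age_y) + sigma_spline(age)
    L    = l0 + nu_spline(age)

The height term is dropped (b = None) for the FEV1/FVC ratio, whose
reference curves depend on age only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .splines import SplineCurve

__all__ = ["LMSCurves", "INDICES", "SEXES"]

INDICES = ("fev1", "fvc", "fev1_fvc", "fef2575")
SEXES = ("male", "female")


@dataclass
class LMSCurves:
    """Evaluatable L/M/S curves for one spirometric index and sex."""

    index: str
    sex: str
    a: float
    b: float | None  # ln(height) coefficient; None = height not in the model
    c: float
    s0: float
    l0: float
    s1: float = 0.0
    mu_spline: SplineCurve | None = None
    sigma_spline: SplineCurve | None = None
    nu_spline: SplineCurve | None = None
    age_range: tuple[float, float] = (4.0, 82.0)
    height_range: tuple[float, float] | None = None
    external: bool = False
    meta: dict = field(default_factory=dict)

    # -- evaluation ---------------------------------------------------------
    def log_mu(self, age, height=None):
        age = np.asarray(age, float)
        out = self.a + self.c * np.log(age)
        if self.b is not None:
            if height is None:
                raise ValueError(f"model for {self.index} requires height")
            out = out + self.b * np.log(np.asarray(height, float))
        if self.mu_spline is not None:
            out = out + self.mu_spline(age)
        return out

    def M(self, age, height=None):
        return np.exp(self.log_mu(age, height))

    def S(self, age):
        age = np.asarray(age, float)
        out = self.s0 + self.s1 * np.log(age)
        if self.sigma_spline is not None:
            out = out + self.sigma_spline(age)
        return np.exp(out)

    def L(self, age):
        age = np.asarray(age, float)
        out = np.full_like(age, self.l0, dtype=float)
        if self.nu_spline is not None:
            out = out + self.nu_spline(age)
        return out if out.shape else float(out)

    def lms_at(self, age, height=None):
        """(M, S, L) arrays at the given covariates."""
        return self.M(age, height), self.S(age), self.L(age)

    def in_hull(self, age, height=None):
        """True where covariates fall inside the documented fitting hull."""
        age = np.asarray(age, float)
        ok = (age >= self.age_range[0]) & (age <= self.age_range[1])
        if height is not None and self.height_range is not None and self.b is not None:
            h = np.asarray(height, float)
            ok = ok & (h >= self.height_range[0]) & (h <= self.height_range[1])
        return ok

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "index": self.index,
            "sex": self.sex,
            "a": float(self.a),
            "b": None if self.b is None else float(self.b),
            "c": float(self.c),
            "s0": float(self.s0),
            "s1": float(self.s1),
            "l0": float(self.l0),
            "age_range": [float(x) for x in self.age_range],
            "external": bool(self.external),
        }
        if self.height_range is not None:
            d["height_range"] = [float(x) for x in self.height_range]
        for name in ("mu_spline", "sigma_spline", "nu_spline"):
            curve = getattr(self, name)
            if curve is not None:
                d[name] = curve.to_dict()
        if self.meta:
            d["meta"] = dict(self.meta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LMSCurves":
        kw = dict(
            index=d["index"],
            sex=d["sex"],
            a=d["a"],
            b=d.get("b"),
            c=d["c"],
            s0=d["s0"],
            s1=d.get("s1", 0.0),
            l0=d["l0"],
            age_range=tuple(d.get("age_range", (4.0, 82.0))),
            external=bool(d.get("external", False)),
            meta=dict(d.get("meta", {})),
        )
        if d.get("height_range") is not None:
            kw["height_range"] = tuple(d["height_range"])
        for name in ("mu_spline", "sigma_spline", "nu_spline"):
            if d.get(name) is not None:
                kw[name] = SplineCurve.from_dict(d[name])
        return cls(**kw)

    # -- validity -----------------------------------------------------------
    def lln_defined_margin(self, n_grid: int = 201) -> float:
        """min over an age grid of 1 - 1.645*L*S; must stay > 0 for the LLN."""
        ages = np.linspace(self.age_range[0], self.age_range[1], n_grid)
        return float(np.min(1.0 - 1.645 * self.L(ages) * self.S(ages)))
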