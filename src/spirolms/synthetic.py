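"""Synthetic spirometry cohorts drawn from a known LMS ground truth.

The study population this emulates is a healthy urban cohort spanning ages
4-82 with both sexes; no raw data are deposited, so validation runs on
cohorts generated here.  Each subject gets age (uniform over the configured
range), height (sex-specific growth-curve mean plus Gaussian noise), weight
(BMI-based, carried for I/O fidelity but unused by the models) and four
spirometric indices drawn independently from the true BCCG-LMS model at the
subject's covariates.  Everything is reproducible from a single seed.

The default truth is calibrated so that adult medians bracket the source
population's reported means (male FEV1 ~3.65 L at age 38/172 cm, female
~2.63 L at age 45/156 cm) with realistic age profiles: a pediatric rise,
a plateau in the twenties, and a slow decline thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import bccg
from .errors import ConfigurationError, DomainError
from .model import INDICES, SEXES, LMSCurves
from .splines import SplineCurve

__all__ = [
    "CohortConfig",
    "HeightModel",
    "TrueLMSModel",
    "default_truth",
    "generate_cohort",
    "population_index_mean",
]

SEX_CODE = {"male": "M", "female": "F"}
COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "height",
    "weight",
    "fev1",
    "fvc",
    "fev1_fvc",
    "fef2575",
]

# Growth-curve anchors: mean standing height (cm) by age, flat beyond 21 y.
_HEIGHT_ANCHORS = {
    "male": ([4, 8, 12, 14, 16, 18, 21], [103, 127, 147, 160, 169, 171.5, 172]),
    "female": ([4, 8, 12, 14, 16, 18, 21], [102, 126, 149, 156, 158, 158.5, 158]),
}
_HEIGHT_SD = {"male": 6.0, "female": 5.5}
_ADULT_BMI = {"male": 25.8, "female": 27.8}


class HeightModel:
    """Age-conditional height: monotone growth curve to 21 y, constant after."""

    def __init__(self, sex: str, anchors=None, sd: float | None = None):
        ages, heights = anchors if anchors is not None else _HEIGHT_ANCHORS[sex]
        self.sex = sex
        self.anchor_ages = np.asarray(ages, float)
        self.anchor_heights = np.asarray(heights, float)
        self.sd = float(_HEIGHT_SD[sex] if sd is None else sd)
        self._interp = PchipInterpolator(self.anchor_ages, self.anchor_heights)

    def mean(self, age):
        age = np.clip(np.asarray(age, float), self.anchor_ages[0], self.anchor_ages[-1])
        return self._interp(age)

    def sample(self, age, rng: np.random.Generator):
        return self.mean(age) + rng.normal(0.0, self.sd, size=np.shape(age))

    def to_dict(self):
        return {
            "sex": self.sex,
            "anchor_ages": self.anchor_ages.tolist(),
            "anchor_heights": self.anchor_heights.tolist(),
            "sd": self.sd,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["sex"], (d["anchor_ages"], d["anchor_heights"]), d["sd"])


@dataclass
class CohortConfig:
    """Configuration for one synthetic cohort.

    n_per_sex may be a single integer or a {"male": n, "female": n} mapping
    (the source study enrolled roughly twice as many women as men).
    """

    n_per_sex: int | dict = 300
    age_range: tuple[float, float] = (4.0, 82.0)
    seed: int = 0
    height_models: dict = field(default_factory=dict)
    enforce_fev1_le_fvc: bool = False

    def n_for(self, sex: str) -> int:
        n = self.n_per_sex[sex] if isinstance(self.n_per_sex, dict) else self.n_per_sex
        return int(n)

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (3.0 <= lo < hi <= 95.0):
            raise ConfigurationError(
                f"age_range must be increasing and within [3, 95], got {self.age_range}"
            )
        for sex in SEXES:
            if self.n_for(sex) <= 0:
                raise ConfigurationError(f"n_per_sex must be positive, got {self.n_per_sex}")

    def height_model(self, sex: str) -> HeightModel:
        return self.height_models.get(sex) or HeightModel(sex)


class TrueLMSModel:
    """A set of ground-truth LMS curves, one per (sex, index)."""

    def __init__(self, curves: dict[tuple[str, str], LMSCurves], meta: dict | None = None):
        self.curves = dict(curves)
        self.meta = dict(meta or {})

    def get(self, sex: str, index: str) -> LMSCurves:
        try:
            return self.curves[(sex, index)]
        except KeyError:
            raise DomainError(f"no true model for sex={sex!r}, index={index!r}") from None

    def items(self):
        return self.curves.items()

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "curves": [c.to_dict() for c in self.curves.values()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueLMSModel":
        curves = {}
        for cd in d["curves"]:
            c = LMSCurves.from_dict(cd)
            curves[(c.sex, c.index)] = c
        return cls(curves, d.get("meta"))


# ---------------------------------------------------------------------------
# Default truth calibration
# ---------------------------------------------------------------------------

# Median anchors (age -> median at the sex's mean height for that age).
_ANCHOR_AGES = np.array([6.0, 10.0, 14.0, 18.0, 25.0, 38.0, 50.0, 65.0, 80.0])

_M_ANCHORS = {
    ("male", "fev1"): [1.35, 2.00, 3.00, 4.10, 4.25, 3.85, 3.45, 2.95, 2.50],
    ("female", "fev1"): [1.25, 1.90, 2.80, 3.10, 3.15, 2.95, 2.70, 2.30, 2.00],
    ("male", "fev1_fvc"): [0.870, 0.860, 0.855, 0.850, 0.840, 0.825, 0.810, 0.790, 0.760],
    ("female", "fev1_fvc"): [0.880, 0.870, 0.865, 0.860, 0.850, 0.835, 0.820, 0.800, 0.770],
    ("male", "fef2575"): [1.40, 2.10, 3.30, 4.30, 4.50, 4.00, 3.40, 2.70, 2.00],
    ("female", "fef2575"): [1.30, 1.95, 3.00, 3.40, 3.50, 3.10, 2.75, 2.30, 1.70],
}
# FVC anchors follow FEV1 / ratio so the three stay mutually consistent.
for _sex in SEXES:
    _M_ANCHORS[(_sex, "fvc")] = [
        f / r for f, r in zip(_M_ANCHORS[(_sex, "fev1")], _M_ANCHORS[(_sex, "fev1_fvc")])
    ]

#: ln(height) coefficient of the true median model, per index (None = no height term).
_TRUE_B = {"fev1": 2.0, "fvc": 2.0, "fev1_fvc": None, "fef2575": 1.3}

#: Coefficient of variation at ages 4 and 40 (log-linear in between and beyond).
_TRUE_S = {
    "fev1": (0.150, 0.115),
    "fvc": (0.150, 0.115),
    "fev1_fvc": (0.090, 0.072),
    "fef2575": (0.300, 0.260),
}

#: Constant Box-Cox power per index (mild right skew; ratio is left-skewed).
_TRUE_L = {"fev1": 0.9, "fvc": 0.9, "fev1_fvc": 1.5, "fef2575": 0.9}


def _calibrate_curves(sex: str, index: str, height_model: HeightModel) -> LMSCurves:
    """Decompose the anchor medians into a + c*ln(age) + spline(age) (+ b*ln(h))."""
    b = _TRUE_B[index]
    targets = np.log(np.asarray(_M_ANCHORS[(sex, index)], float))
    g = targets.copy()
    if b is not None:
        g = g - b * np.log(height_model.mean(_ANCHOR_AGES))
    X = np.column_stack([np.ones_like(_ANCHOR_AGES), np.log(_ANCHOR_AGES)])
    coef, *_ = np.linalg.lstsq(X, g, rcond=None)
    resid = g - X @ coef
    s4, s40 = _TRUE_S[index]
    s1 = np.log(s40 / s4) / np.log(40.0 / 4.0)
    s0 = np.log(s4) - s1 * np.log(4.0)
    return LMSCurves(
        index=index,
        sex=sex,
        a=float(coef[0]),
        b=b,
        c=float(coef[1]),
        s0=float(s0),
        s1=float(s1),
        l0=float(_TRUE_L[index]),
        mu_spline=SplineCurve(_ANCHOR_AGES, resid),
        age_range=(4.0, 82.0),
        meta={"source": "default synthetic truth"},
    )


def default_truth() -> TrueLMSModel:
    """The documented fixed ground-truth model for both sexes, ages 4-82."""
    curves = {}
    for sex in SEXES:
        hm = HeightModel(sex)
        for index in INDICES:
            curves[(sex, index)] = _calibrate_curves(sex, index, hm)
    truth = TrueLMSModel(curves, meta={"name": "default_truth"})
    for c in truth.curves.values():
        margin = c.lln_defined_margin()
        if margin <= 0:
            raise AssertionError(f"LLN undefined for truth {c.sex}/{c.index}: {margin}")
    return truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _bmi_mean(age, sex):
    frac = np.clip((np.asarray(age, float) - 4.0) / 21.0, 0.0, 1.0)
    return 15.5 + (_ADULT_BMI[sex] - 15.5) * frac


def _draw_index(rng, curves: LMSCurves, age, height):
    M, S, L = curves.lms_at(age, height if curves.b is not None else None)
    z = rng.standard_normal(len(age))
    # redraw the (practically never occurring) draws outside the BCCG support
    for _ in range(100):
        bad = 1.0 + L * S * z <= 0
        if not np.any(bad):
            break
        z[bad] = rng.standard_normal(int(np.sum(bad)))
    return bccg.y_from_z(z, (M, S, L))


def generate_cohort(config: CohortConfig, truth: TrueLMSModel) -> pd.DataFrame:
    """Simulate a cohort table; fully reproducible from ``config.seed``.

    The four indices are drawn independently per subject (each index has its
    own reference model, as in practice); the physiological coupling
    FEV1 <= FVC is only imposed when ``config.enforce_fev1_le_fvc`` is set,
    by redrawing violating pairs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    frames = []
    offset = 0
    for sex in SEXES:
        for index in INDICES:
            c = truth.get(sex, index)
            if lo < c.age_range[0] or hi > c.age_range[1]:
                raise DomainError(
                    f"truth for {sex}/{index} covers ages {c.age_range}, "
                    f"cohort requests {config.age_range}"
                )
        n = config.n_for(sex)
        hm = config.height_model(sex)
        age = rng.uniform(lo, hi, n)
        height = hm.sample(age, rng)
        bmi = np.clip(rng.normal(_bmi_mean(age, sex), 4.5), 12.0, None)
        weight = bmi * (height / 100.0) ** 2
        values = {
            index: _draw_index(rng, truth.get(sex, index), age, height) for index in INDICES
        }
        if config.enforce_fev1_le_fvc:
            for _ in range(100):
                bad = values["fev1"] > values["fvc"]
                if not np.any(bad):
                    break
                for index in ("fev1", "fvc"):
                    c = truth.get(sex, index)
                    sub = _draw_index(rng, c, age[bad], height[bad])
                    values[index] = values[index].copy()
                    values[index][bad] = sub
        frame = pd.DataFrame(
            {
                "subject_id": [f"S{offset + i:05d}" for i in range(n)],
                "sex": SEX_CODE[sex],
                "age": age,
                "height": height,
                "weight": weight,
                **{index: values[index] for index in INDICES},
            }
        )
        frames.append(frame)
        offset += n
    return pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Population moments (quadrature oracle for calibration checks)
# ---------------------------------------------------------------------------

def population_index_mean(
    curves: LMSCurves,
    height_model: HeightModel,
    age_range: tuple[float, float] = (4.0, 82.0),
    n_age: int = 201,
    n_herm: int = 40,
) -> float:
    """E[index] under uniform age, Gaussian height and the BCCG model.

    Computed by tensor quadrature (trapezoid over age x Gauss-Hermite over
    the height and measurement deviates), independent of the sampler.
    """
    ages = np.linspace(age_range[0], age_range[1], n_age)
    hz, hw = np.polynomial.hermite_e.hermegauss(n_herm)
    hw = hw / hw.sum()
    means = np.empty(n_age)
    for i, a in enumerate(ages):
        h = height_model.mean(a) + height_model.sd * hz
        M, S, L = curves.lms_at(np.full(n_herm, a), h if curves.b is not None else None)
        # E[(1 + L*S*Z)^(1/L)] over Z for each height node
        arg = 1.0 + np.outer(L * S, hz)
        arg = np.where(arg > 0, arg, np.nan)
        ey = np.nansum(np.power(arg, 1.0 / L[:, None]) * hw[None, :], axis=1)
        means[i] = float(np.sum(M * ey * hw))
    return float(np.trapezoid(means, ages) / (age_range[1] - age_range[0]))
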