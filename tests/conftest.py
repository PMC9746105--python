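import numpy as np
import pytest

import spirolms as sp
from spirolms.model import INDICES, SEXES, LMSCurves
from spirolms.synthetic import CohortConfig, TrueLMSModel

#: study-scale sex split (about twice as many women as men, ages 4-82)
STUDY_N = {"male": 204, "female": 418}


@pytest.fixture(scope="session")
def truth():
    return sp.default_truth()


@pytest.fixture(scope="session")
def study_cohort(truth):
    return sp.generate_cohort(CohortConfig(n_per_sex=STUDY_N, seed=20190531), truth)


@pytest.fixture(scope="session")
def fev1_female_fit(study_cohort):
    return sp.fit_lms(study_cohort, sp.ModelSpec("fev1", "female", df_m=5))


def constant_truth(M=3.0, S=0.1, L=1.0) -> TrueLMSModel:
    """A degenerate truth with the same constant (M, S, L) for every index/sex.

    Useful as an analytically tractable ground truth: with L = 1 the BCCG
    reduces to a normal with mean M and SD M*S.
    """
    curves = {}
    for sex in SEXES:
        for index in INDICES:
            curves[(sex, index)] = LMSCurves(
                index=index, sex=sex,
                a=float(np.log(M)), b=None, c=0.0,
                s0=float(np.log(S)), s1=0.0, l0=float(L),
            )
    return TrueLMSModel(curves, meta={"name": "constant"})


def loglinear_truth(a=-9.0, b=2.0, c=0.12, S=0.1, L=1.0) -> TrueLMSModel:
    """Truth with ln M = a + b*ln(height) + c*ln(age) and no spline curvature."""
    curves = {}
    for sex in SEXES:
        for index in INDICES:
            curves[(sex, index)] = LMSCurves(
                index=index, sex=sex,
                a=a, b=b, c=c,
                s0=float(np.log(S)), s1=0.0, l0=float(L),
            )
    return TrueLMSModel(curves, meta={"name": "loglinear"})
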