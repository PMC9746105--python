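"""LMS fitting: recovery of a known truth, model selection, diagnostics."""

import numpy as np
import pytest

import spirolms as sp
from spirolms import fitting
from spirolms.errors import ConfigurationError, FitError

from conftest import loglinear_truth


@pytest.fixture(scope="module")
def loglinear_cohort():
    t = loglinear_truth(a=-9.0, b=2.0, c=0.12, S=0.1, L=1.0)
    return t, sp.generate_cohort(sp.CohortConfig(n_per_sex=2000, seed=5), t)


def test_parameter_recovery_on_loglinear_truth(loglinear_cohort):
    # Truth has no spline curvature, constant S and L=1: the fitted height
    # and age elasticities must land within 3 SE of truth (SE from the
    # Gaussian log-scale information), S within 10%.
    _, cohort = loglinear_cohort
    fit = fitting.fit_lms(cohort, fitting.ModelSpec("fev1", "male", df_m=0))
    rows = cohort[cohort["sex"] == "M"]
    X = np.column_stack(
        [np.ones(len(rows)), np.log(rows["height"]), np.log(rows["age"])]
    )
    se = 0.1 * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
    assert fit.converged
    assert fit.curves.b == pytest.approx(2.0, abs=3 * se[1])
    assert fit.curves.c == pytest.approx(0.12, abs=3 * se[2])
    assert fit.curves.S(30.0) == pytest.approx(0.1, rel=0.10)


def test_refit_is_deterministic(loglinear_cohort):
    _, cohort = loglinear_cohort
    spec = fitting.ModelSpec("fvc", "female", df_m=2)
    a = fitting.fit_lms(cohort, spec)
    b = fitting.fit_lms(cohort, spec)
    assert abs(a.aic - b.aic) < 1e-6


def test_scale_equivariance(loglinear_cohort):
    # Multiplying the measurand by k must scale M by k and leave S, L alone.
    _, cohort = loglinear_cohort
    k = 2.5
    scaled = cohort.copy()
    scaled["fev1"] = scaled["fev1"] * k
    f1 = fitting.fit_lms(cohort, fitting.ModelSpec("fev1", "male", df_m=2))
    f2 = fitting.fit_lms(scaled, fitting.ModelSpec("fev1", "male", df_m=2))
    ages = np.linspace(5.0, 80.0, 20)
    h = np.full_like(ages, 170.0)
    # exact ML is scale-equivariant; the residual slack is optimizer tolerance
    assert np.allclose(f2.curves.M(ages, h), k * f1.curves.M(ages, h), rtol=1e-3)
    assert np.allclose(f2.curves.S(ages), f1.curves.S(ages), rtol=1e-2)
    assert f2.curves.l0 == pytest.approx(f1.curves.l0, abs=0.05)


def test_likelihood_ascent_and_nesting(study_cohort):
    fit = sp.fit_lms(study_cohort, fitting.ModelSpec("fvc", "male", df_m=3))
    trace = np.asarray(fit.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-6)  # optimizer only climbs
    smaller = sp.fit_lms(study_cohort, fitting.ModelSpec("fvc", "male", df_m=0))
    assert fit.loglik >= smaller.loglik - 1e-6  # added df never loses likelihood


def test_selection_prefers_minimum_df_without_curvature(loglinear_cohort):
    _, cohort = loglinear_cohort
    best, table = fitting.select_model(
        cohort, fitting.spec_grid("fev1", "male", df_m_grid=(0, 2, 4))
    )
    assert best.spec.df_m == 0
    assert len(table) == 3
    assert np.allclose(table["aic"], -2 * table["loglik"] + 2 * table["edf"])
    assert np.allclose(
        table["sbc"], -2 * table["loglik"] + np.log(table["n_obs"]) * table["edf"]
    )


def test_selection_single_spec_passthrough(study_cohort):
    spec = fitting.ModelSpec("fev1_fvc", "female", df_m=2)
    direct = sp.fit_lms(study_cohort, spec)
    best, table = fitting.select_model(study_cohort, [spec])
    assert len(table) == 1
    assert best.aic == pytest.approx(direct.aic, abs=1e-9)


def test_ratio_model_excludes_height_by_default(study_cohort):
    fit = sp.fit_lms(study_cohort, fitting.ModelSpec("fev1_fvc", "male", df_m=2))
    assert fit.curves.b is None
    override = fitting.ModelSpec("fev1_fvc", "male", df_m=2, use_height=True)
    assert sp.fit_lms(study_cohort, override).curves.b is not None


def test_errors_and_failure_reporting(study_cohort, truth):
    with pytest.raises(ConfigurationError):
        fitting.ModelSpec("pef", "male")
    with pytest.raises(ConfigurationError):
        fitting.ModelSpec("fev1", "male", df_m=-1)
    tiny = sp.generate_cohort(sp.CohortConfig(n_per_sex=30, seed=1), truth)
    with pytest.raises(ConfigurationError, match=">= 50 subjects"):
        sp.fit_lms(tiny, fitting.ModelSpec("fev1", "male"))
    with pytest.raises(FitError, match="all candidate specs failed"):
        fitting.select_model(tiny, [fitting.ModelSpec("fev1", "male")])


def test_diagnostics_on_well_specified_fit(truth, fev1_female_fit, study_cohort):
    diag = sp.diagnose(fev1_female_fit, study_cohort)
    z = diag.residual_z
    assert len(z) == fev1_female_fit.n_obs
    # exact z-scores of a well-specified fit are ~N(0,1)
    assert abs(np.mean(z)) < 0.05
    assert 0.95 < np.std(z, ddof=1) < 1.05
    assert 0.0 <= diag.normality_p <= 1.0

    # parametric check at large n: residuals of data drawn from the fitted
    # model itself stay within the +/-5 clinical residual range
    big = sp.generate_cohort(sp.CohortConfig(n_per_sex=5000, seed=77), truth)
    refit = sp.fit_lms(big, fitting.ModelSpec("fev1", "female", df_m=5))
    d2 = sp.diagnose(refit, big)
    assert d2.max_abs_residual_z < 5.0
    # Q-Q points of near-normal residuals hug the identity line
    theo, obs = d2.qq_points[:, 0], d2.qq_points[:, 1]
    inner = np.abs(theo) < 2.5
    assert np.max(np.abs(theo[inner] - obs[inner])) < 0.25
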