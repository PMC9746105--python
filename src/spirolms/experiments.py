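"""Replicated validation experiments on synthetic cohorts.

These are the study-scale simulation experiments the package uses to
validate the whole pipeline against its own ground truth:

* Z-score calibration of refitted equations (the fitting sample scored
  under its own equations has group Z-means indistinguishable from zero);
* the residual-range check (max |exact z| within the +/-5 clinical band);
* recovery of the true median curve and the 5th-centile coverage of the
  fitted LLN on fresh draws.

Cohorts are generated at the scale of the emulated study (418 females,
204 males, ages 4-82).  Fits use an age-spline with 5 free coefficients
for the median curve — ample for the smooth pediatric-rise/adult-decline
profile over an 80-year span while keeping each fit under a second.  All
replication seeds derive from one root seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np

from . import fitting, reference
from .analysis import DEFAULT_SCHEME, z_summary
from .model import INDICES, SEXES
from .synthetic import SEX_CODE, CohortConfig, HeightModel, TrueLMSModel, default_truth, generate_cohort

__all__ = [
    "STUDY_N",
    "VALIDATION_DF_M",
    "study_config",
    "refit_cohort",
    "zscore_calibration",
    "residual_range",
    "median_curve_recovery",
]

#: Sex split of the emulated study population.
STUDY_N = {"male": 204, "female": 418}

#: Free spline coefficients for the median age-curve in validation fits.
VALIDATION_DF_M = 5

#: Age-group size above which a group's t-test is considered well-powered.
LARGE_GROUP_N = 30


def _child_seed(root: int, stream: int, rep: int) -> int:
    return int(np.random.SeedSequence([root, stream, rep]).generate_state(1)[0] % (2**31))


def study_config(seed: int) -> CohortConfig:
    return CohortConfig(n_per_sex=dict(STUDY_N), age_range=(4.0, 82.0), seed=seed)


def refit_cohort(cohort, indices=INDICES, df_m: int = VALIDATION_DF_M):
    """Fit every (index, sex) model on one cohort; returns {(sex, index): fit}."""
    return {
        (sex, index): fitting.fit_lms(
            cohort, fitting.ModelSpec(index, sex, df_m=df_m)
        )
        for index in indices
        for sex in SEXES
    }


def zscore_calibration(
    seed: int,
    n_rep: int = 10,
    indices=INDICES,
    truth: TrueLMSModel | None = None,
) -> dict:
    """Refit replicate cohorts and score each fitting sample under its own equations.

    Returns per-index grand mean of the paper-mode Z (averaged over
    replicates) and the pooled one-sample t-test p-values of the age-group
    means, split by group size.
    """
    truth = truth or default_truth()
    grand = {index: [] for index in indices}
    pvals_large, pvals_all = [], []
    for rep in range(n_rep):
        cohort = generate_cohort(study_config(_child_seed(seed, 1, rep)), truth)
        fits = refit_cohort(cohort, indices=indices)
        for index in indices:
            zs = []
            for sex in SEXES:
                pred = reference.predict_table(fits[(sex, index)].curves, cohort, z_mode="paper")
                zs.append(pred)
                summary = z_summary(pred, DEFAULT_SCHEME)
                occupied = summary[summary["n"] > 1]
                pvals_all.extend(occupied["t_p"].tolist())
                pvals_large.extend(occupied.loc[occupied["n"] >= LARGE_GROUP_N, "t_p"].tolist())
            z_all = np.concatenate([p["Z"].dropna().to_numpy() for p in zs])
            grand[index].append(float(np.mean(z_all)))
    return {
        "grand_mean_z": {index: float(np.mean(v)) for index, v in grand.items()},
        "grand_mean_z_reps": grand,
        "pvals_large_groups": np.asarray(pvals_large),
        "pvals_all_groups": np.asarray(pvals_all),
    }


def residual_range(
    seed: int,
    n_rep: int = 20,
    index: str = "fev1",
    truth: TrueLMSModel | None = None,
) -> np.ndarray:
    """Max |exact residual z| on the fitting sample, per replicate cohort.

    One index, both sexes fitted separately; the replicate's statistic is
    the max over the whole cohort (n ~ 622).
    """
    truth = truth or default_truth()
    out = []
    for rep in range(n_rep):
        cohort = generate_cohort(study_config(_child_seed(seed, 2, rep)), truth)
        worst = 0.0
        for sex in SEXES:
            fit = fitting.fit_lms(cohort, fitting.ModelSpec(index, sex, df_m=VALIDATION_DF_M))
            diag = fitting.diagnose(fit, cohort)
            worst = max(worst, diag.max_abs_residual_z)
        out.append(worst)
    return np.asarray(out)


def median_curve_recovery(
    seed: int,
    n_rep: int = 20,
    index: str = "fev1",
    truth: TrueLMSModel | None = None,
) -> dict:
    """Relative RMSE of the fitted median curve and fresh-draw LLN coverage.

    Per replicate: fit both sexes on a study-scale cohort; evaluate M on a
    test grid of ages 6-80 at the growth-curve mean height and +/-1 SD
    (inside the covariate hull); score a fresh cohort from the truth
    against the fitted LLN.
    """
    truth = truth or default_truth()
    ages = np.linspace(6.0, 80.0, 38)
    rmse, coverage = [], []
    for rep in range(n_rep):
        cohort = generate_cohort(study_config(_child_seed(seed, 3, rep)), truth)
        fresh = generate_cohort(study_config(_child_seed(seed, 4, rep)), truth)
        errs, n_below, n_tot = [], 0, 0
        for sex in SEXES:
            fit = fitting.fit_lms(cohort, fitting.ModelSpec(index, sex, df_m=VALIDATION_DF_M))
            true_c = truth.get(sex, index)
            hm = HeightModel(sex)
            for shift in (-1.0, 0.0, 1.0):
                h = hm.mean(ages) + shift * hm.sd
                errs.append(fit.curves.M(ages, h) / true_c.M(ages, h) - 1.0)
            rows = fresh[fresh["sex"] == SEX_CODE[sex]]
            M, S, L = fit.curves.lms_at(
                rows["age"].to_numpy(), rows["height"].to_numpy()
            )
            lln_v = np.asarray(reference.lln((M, S, L)))
            n_below += int((rows[index].to_numpy() < lln_v).sum())
            n_tot += len(rows)
        rmse.append(float(np.sqrt(np.mean(np.concatenate(errs) ** 2))))
        coverage.append(100.0 * n_below / n_tot)
    return {"rmse": np.asarray(rmse), "coverage_pct": np.asarray(coverage)}
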