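"""Age-group Z summaries, below-LLN tables, Bland-Altman agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spirolms as sp
from spirolms import reference
from spirolms.analysis import (
    DEFAULT_SCHEME,
    AgeGroupScheme,
    below_lln_table,
    bland_altman,
    z_summary,
)
from spirolms.errors import InputError


def _pred_frame(z, sex="M", age=35.0):
    n = len(z)
    return pd.DataFrame(
        {"sex": sex, "age": np.full(n, age), "Z": np.asarray(z, float)}
    )


def test_default_scheme_bin_assignment():
    # gappy conventional labels resolve to contiguous half-open bins
    ages = [9.99, 10.0, 21.5, 22.0, 69.9, 70.0, 95.0]
    got = list(DEFAULT_SCHEME.assign(ages))
    assert got == ["< 10", "10-21", "10-21", "22-29", "60-69", "> 70", "> 70"]
    with pytest.raises(InputError):
        AgeGroupScheme([("a", 0, 10), ("b", 12, 20)])  # gap


def test_z_summary_degenerate_groups():
    s = z_summary(_pred_frame(np.zeros(12)))
    row = s[(s["n"] > 0)].iloc[0]
    assert row["mean_z"] == 0.0 and row["t_p"] == 1.0  # zero variance at the null
    assert not row["clinically_significant"]

    s2 = z_summary(_pred_frame(np.full(12, 0.6)))
    row2 = s2[s2["n"] > 0].iloc[0]
    assert row2["clinically_significant"]  # |mean| > 0.5 rule

    # empty groups are emitted, not dropped
    assert set(s["age_group"]) == set(DEFAULT_SCHEME.labels)
    assert (s.loc[s["age_group"] == "< 10", "n"] == 0).all()


def test_z_summary_matches_direct_t_test():
    rng = np.random.default_rng(4)
    z = rng.normal(0.1, 1.0, 200)
    s = z_summary(_pred_frame(z))
    row = s[s["n"] > 0].iloc[0]
    t = stats.ttest_1samp(z, 0.0)
    assert row["t_p"] == pytest.approx(t.pvalue, rel=1e-12)
    lo, hi = stats.t.interval(0.95, len(z) - 1, loc=np.mean(z), scale=stats.sem(z))
    assert row["ci95_lo"] == pytest.approx(lo, rel=1e-9)
    assert row["ci95_hi"] == pytest.approx(hi, rel=1e-9)
    assert row["ci95_lo"] < row["mean_z"] < row["ci95_hi"]


def test_t_test_calibration_under_the_null():
    # p-values of one-sample tests on standard-normal Z are uniform(0,1)
    rng = np.random.default_rng(11)
    pvals = []
    for _ in range(200):
        s = z_summary(_pred_frame(rng.standard_normal(10_000)))
        pvals.append(float(s.loc[s["n"] > 0, "t_p"].iloc[0]))
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_below_lln_counts_and_margins(truth):
    cohort = sp.generate_cohort(sp.CohortConfig(n_per_sex=4000, seed=13), truth)
    preds = []
    for sex in ("male", "female"):
        preds.append(reference.predict_table(truth.get(sex, "fev1_fvc"), cohort))
    pred = pd.concat(preds, ignore_index=True)

    table = below_lln_table(pred)
    total = table[(table["age_group"] == "total") & (table["sex"] == "all")].iloc[0]
    # scored against its own true model: ~5% below the LLN overall
    assert total["pct_below_lln"] == pytest.approx(5.0, abs=1.0)
    # sexes sum to the total column in every age group
    for label in DEFAULT_SCHEME.labels:
        sub = table[table["age_group"] == label]
        assert (
            sub.loc[sub["sex"] == "all", "n_below_lln"].iloc[0]
            == sub.loc[sub["sex"] != "all", "n_below_lln"].sum()
        )
    assert total["cell"] == f"{total['n_below_lln']} ({total['pct_below_lln']:.1f})"

    # everyone exactly at the median: nothing below the LLN
    at_median = pred.copy()
    at_median["observed"] = at_median["M"]
    none = below_lln_table(at_median)
    assert (none["n_below_lln"] == 0).all()


def test_bland_altman_closed_forms():
    a = np.arange(10.0)
    same = bland_altman(a, a.copy())
    assert same.mean_diff == 0.0 and same.sd_diff == 0.0

    offset = bland_altman(a, a + 1.0)
    assert offset.mean_diff == pytest.approx(-1.0)
    assert offset.sd_diff == 0.0
    assert offset.loa == (pytest.approx(-1.0), pytest.approx(-1.0))

    rng = np.random.default_rng(8)
    d = rng.normal(0.5, 0.2, 10_000)
    st_ = bland_altman(d, np.zeros_like(d))
    assert st_.mean_diff == pytest.approx(0.5, abs=0.01)
    assert st_.loa[0] == pytest.approx(0.108, abs=0.02)
    assert st_.loa[1] == pytest.approx(0.892, abs=0.02)
    # limits of agreement hold ~95% of normal differences
    inside = np.mean((d > st_.loa[0]) & (d < st_.loa[1]))
    assert inside == pytest.approx(0.95, abs=0.01)

    with pytest.raises(InputError):
        bland_altman(a, a[:5])


def test_group_means_not_significant_under_own_fit(study_cohort, fev1_female_fit):
    # Refitting-sample Z under the cohort's own equations: group means are
    # statistically indistinguishable from zero in at least 7 of 8 bins.
    pred = reference.predict_table(fev1_female_fit.curves, study_cohort)
    s = z_summary(pred)
    occupied = s[s["n"] > 1]
    n_ok = int((occupied["t_p"] > 0.05).sum())
    assert n_ok >= len(occupied) - 1
    assert not occupied["clinically_significant"].any()
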