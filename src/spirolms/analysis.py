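"""Cohort-level comparison battery for reference equations.

Mirrors the standard validation workflow for spirometry references:
age-group Z-score summaries with one-sample t-tests against zero (a mean
Z outside +/-0.5 is flagged clinically significant, the GLI working rule),
frequency tables of observations below the LLN, and Bland-Altman agreement
between two reference models' predictions.

Age bins follow the conventional decade-ish grouping <10, 10-21, 22-29,
..., >70, implemented as half-open intervals [0,10), [10,22), [22,30),
[30,40), [40,50), [50,60), [60,70), [70,inf).  No multiple-testing
correction is applied across groups or indices (none is customary in this
validation setting); output metadata says so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "AgeGroupScheme",
    "DEFAULT_SCHEME",
    "AgreementStats",
    "z_summary",
    "below_lln_table",
    "bland_altman",
    "CLINICAL_Z_THRESHOLD",
]

#: |mean Z| beyond which a group-level disagreement is called clinically significant.
CLINICAL_Z_THRESHOLD = 0.5


class AgeGroupScheme:
    """Ordered, non-overlapping half-open age bins [min, max)."""

    def __init__(self, bins: list[tuple[str, float, float]]):
        if not bins:
            raise InputError("scheme needs at least one bin")
        for (_, lo, hi), (_, lo2, _hi2) in zip(bins, bins[1:]):
            if hi != lo2 or lo >= hi:
                raise InputError("bins must be increasing, contiguous half-open intervals")
        self.bins = list(bins)

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bins]

    def assign(self, ages) -> pd.Categorical:
        ages = np.asarray(ages, float)
        edges = [b[1] for b in self.bins] + [self.bins[-1][2]]
        idx = np.searchsorted(edges, ages, side="right") - 1
        idx = np.where((ages >= edges[0]) & (ages < edges[-1]), idx, -1)
        labels = np.array(self.labels + ["(out of range)"], dtype=object)
        return pd.Categorical(labels[idx], categories=self.labels, ordered=True)


DEFAULT_SCHEME = AgeGroupScheme(
    [
        ("< 10", 0.0, 10.0),
        ("10-21", 10.0, 22.0),
        ("22-29", 22.0, 30.0),
        ("30-39", 30.0, 40.0),
        ("40-49", 40.0, 50.0),
        ("50-59", 50.0, 60.0),
        ("60-69", 60.0, 70.0),
        ("> 70", 70.0, np.inf),
    ]
)


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired differences (a - b)."""

    index: str
    sex: str
    n: int
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]


def _one_sample_t(z: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Two-sided one-sample t-test vs 0 and the exact t-based CI95.

    Convention for degenerate input: zero variance at the null (all values
    exactly 0) gives p = 1; zero variance off the null gives p = 0.
    """
    n = len(z)
    mean = float(np.mean(z))
    sd = float(np.std(z, ddof=1)) if n > 1 else 0.0
    if sd == 0.0 or n < 2:
        p = 1.0 if mean == 0.0 else 0.0
        return p, (mean, mean)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    p = float(stats.ttest_1samp(z, 0.0).pvalue)
    return p, (mean - tcrit * se, mean + tcrit * se)


def z_summary(
    predictions: pd.DataFrame,
    scheme: AgeGroupScheme = DEFAULT_SCHEME,
    normal_ci: bool = False,
) -> pd.DataFrame:
    """Per (age group, sex) Z-score summaries with one-sample tests vs zero.

    ``predictions`` needs columns sex, age, Z (as produced by
    :func:`spirolms.reference.predict_table`).  Empty groups are emitted
    with n = 0 and NaN statistics, never dropped.  ``normal_ci`` swaps the
    t-based CI95 for the normal approximation.
    """
    df = predictions.copy()
    df["age_group"] = scheme.assign(df["age"])
    rows = []
    sexes = sorted(df["sex"].dropna().unique())
    for label in scheme.labels:
        for sex in sexes:
            z = df.loc[
                (df["age_group"] == label) & (df["sex"] == sex), "Z"
            ].dropna().to_numpy()
            n = len(z)
            if n == 0:
                rows.append(
                    dict(
                        age_group=label, sex=sex, n=0, mean_z=np.nan, sd_z=np.nan,
                        ci95_lo=np.nan, ci95_hi=np.nan, t_p=np.nan,
                        clinically_significant=False,
                    )
                )
                continue
            mean = float(np.mean(z))
            sd = float(np.std(z, ddof=1)) if n > 1 else 0.0
            if normal_ci and n > 1:
                se = sd / np.sqrt(n)
                ci = (mean - 1.96 * se, mean + 1.96 * se)
                p = float(stats.ttest_1samp(z, 0.0).pvalue) if sd > 0 else (1.0 if mean == 0 else 0.0)
            else:
                p, ci = _one_sample_t(z)
            rows.append(
                dict(
                    age_group=label, sex=sex, n=n, mean_z=mean, sd_z=sd,
                    ci95_lo=ci[0], ci95_hi=ci[1], t_p=p,
                    clinically_significant=bool(abs(mean) > CLINICAL_Z_THRESHOLD),
                )
            )
    out = pd.DataFrame(rows)
    out.attrs["multiple_testing_correction"] = "none"
    return out


def below_lln_table(
    predictions: pd.DataFrame, scheme: AgeGroupScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Counts and percentages of observed < LLN per (age group, sex) plus totals.

    ``predictions`` needs columns sex, age, observed, LLN.  The ``cell``
    column formats each entry as "n (pct)" for report-style tables.
    """
    df = predictions.dropna(subset=["observed", "LLN"]).copy()
    df["age_group"] = scheme.assign(df["age"])
    df["below"] = df["observed"] < df["LLN"]
    rows = []
    sexes = sorted(df["sex"].dropna().unique())
    for label in scheme.labels + ["total"]:
        sub_g = df if label == "total" else df[df["age_group"] == label]
        for sex in list(sexes) + ["all"]:
            sub = sub_g if sex == "all" else sub_g[sub_g["sex"] == sex]
            n = len(sub)
            k = int(sub["below"].sum())
            pct = 100.0 * k / n if n else np.nan
            rows.append(
                dict(
                    age_group=label, sex=sex, n=n, n_below_lln=k, pct_below_lln=pct,
                    cell=f"{k} ({pct:.1f})" if n else "0 (-)",
                )
            )
    return pd.DataFrame(rows)


def bland_altman(pred_a, pred_b, index: str = "", sex: str = "") -> AgreementStats:
    """Bland-Altman agreement between two models' paired predictions.

    Differences are taken a - b with the orientation fixed by the caller
    (conventionally a = external reference, b = newly fitted).  Limits of
    agreement are mean_diff +/- 1.96*sd_diff.
    """
    a = np.asarray(pred_a, float)
    b = np.asarray(pred_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError(f"paired predictions must be equal-length 1-d arrays, got {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 2:
        raise InputError("Bland-Altman needs at least 2 complete pairs")
    d = a - b
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    return AgreementStats(
        index=index,
        sex=sex,
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa=(mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff),
    )


def bland_altman_plot(pred_a, pred_b, ax=None, **kwargs):
    """Difference-vs-mean scatter with mean and limit-of-agreement lines."""
    import matplotlib.pyplot as plt

    st = bland_altman(pred_a, pred_b, **kwargs)
    a = np.asarray(pred_a, float)
    b = np.asarray(pred_b, float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=8, alpha=0.5)
    ax.axhline(st.mean_diff, color="k", lw=1)
    for y in st.loa:
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("pairwise mean")
    ax.set_ylabel("difference (a - b)")
    title = " ".join(x for x in (st.index, st.sex) if x)
    if title:
        ax.set_title(title)
    return ax, st
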