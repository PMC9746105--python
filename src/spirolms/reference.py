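"""Evaluating reference models: predicted values, LLN, SD, Z-scores, lookup tables.

Two Z-score definitions coexist and every output says which was used:

``paper`` (default)
    The linear formula used in the source field's clinical practice:
    SD = (M - LLN)/1.645 and Z = (observed - M)/SD, with the literal
    constant 1.645.  Exact at observed = M (Z=0) and observed = LLN
    (Z=-1.645); elsewhere a linear approximation to the Box-Cox scale.

``exact``
    The BCCG transform ((y/M)^L - 1)/(L*S), a standard normal deviate
    under the model, using full-precision Phi^-1(0.95) where needed.

The LLN is the 5th reference percentile,
LLN = exp[ln M + ln(1 - z*L*S)/L] (lognormal limit M*exp(-z*S) at L = 0),
evaluated with the full-precision z = Phi^-1(0.95) so it coincides exactly
with the BCCG 5% quantile; the printed clinical constant 1.645 reproduces
it to ~1e-4 relative on spirometry-like L*S and is available via z_crit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import bccg
from .errors import ConfigurationError, DomainError
from .model import LMSCurves

__all__ = ["Z_LLN", "lln", "sd_paper", "zscore_paper", "predict_table", "predict_subject", "lookup_table"]

#: The rounded normal quantile printed in clinical formulas; used in paper-mode
#: Z-scores.  The LLN itself uses the full-precision Phi^-1(0.95) so that it is
#: exactly the 5th percentile (the printed 1.645 agrees to ~1e-4 relative on
#: spirometry-like L*S; pass ``z_crit=1.645`` to reproduce the rounded value).
Z_LLN = 1.645
_Z95 = float(stats.norm.ppf(0.95))


def lln(p, z_crit: float = _Z95):
    """Lower limit of normal (5th percentile) of a BCCG reference point.

    Evaluates exp[ln M + ln(1 - z*L*S)/L] (lognormal limit M*exp(-z*S) at
    L = 0) with z = Phi^-1(0.95) by default.  Accepts an
    :class:`~spirolms.bccg.LMSPoint` or an (M, S, L) tuple of scalars/arrays.
    Requires 1 - z*L*S > 0 (for L != 0).
    """
    M, S, L = bccg._unpack(p)
    small = np.abs(L) < bccg.L_ZERO_TOL
    arg = 1.0 - z_crit * L * S
    if np.any(~small & (arg <= 0)):
        bad = np.argmin(np.where(small, np.inf, arg))
        raise DomainError(
            "LLN undefined: 1 - z*L*S <= 0 at "
            f"(L={np.ravel(L)[bad]:.4g}, S={np.ravel(S)[bad]:.4g})"
        )
    Lsafe = np.where(small, 1.0, L)
    out = np.where(
        small,
        M * np.exp(-z_crit * S),
        np.exp(np.log(M) + np.log(np.where(arg > 0, arg, 1.0)) / Lsafe),
    )
    return out if out.shape else float(out)


def sd_paper(M, lln_value):
    """The paper-mode SD: (predicted - LLN)/1.645."""
    M = np.asarray(M, float)
    lln_value = np.asarray(lln_value, float)
    if np.any(M <= lln_value):
        raise DomainError("predicted median must exceed the LLN")
    out = (M - lln_value) / Z_LLN
    return out if out.shape else float(out)


def zscore_paper(observed, M, lln_value):
    """Linear Z-score (observed - predicted)/SD with SD = (M - LLN)/1.645."""
    observed = np.asarray(observed, float)
    out = (observed - np.asarray(M, float)) / sd_paper(M, lln_value)
    return out if out.shape else float(out)


def predict_table(
    curves: LMSCurves, data: pd.DataFrame, z_mode: str = "paper"
) -> pd.DataFrame:
    """Per-subject reference predictions for one (index, sex) model.

    ``data`` is a cohort table (only rows of the model's sex are used).
    Returns one row per subject with M, S, L, LLN, SD, Z, percentile and an
    extrapolation flag; Z and percentile are NaN where the observed value is
    missing.
    """
    if z_mode not in ("paper", "exact"):
        raise ConfigurationError("z_mode must be 'paper' or 'exact'")
    from .synthetic import SEX_CODE  # local import to avoid cycle at module load

    rows = data[data["sex"] == SEX_CODE[curves.sex]].copy()
    age = rows["age"].to_numpy(float)
    height = rows["height"].to_numpy(float)
    if np.any(age <= 0) or np.any(height <= 0):
        raise DomainError("age and height must be positive")
    M, S, L = curves.lms_at(age, height if curves.b is not None else None)
    lln_v = np.asarray(lln((M, S, L)))
    sd_v = (M - lln_v) / Z_LLN

    observed = (
        rows[curves.index].to_numpy(float)
        if curves.index in rows.columns
        else np.full(len(rows), np.nan)
    )
    have = np.isfinite(observed) & (observed > 0)
    z = np.full(len(rows), np.nan)
    pct = np.full(len(rows), np.nan)
    if np.any(have):
        if z_mode == "paper":
            z[have] = zscore_paper(observed[have], M[have], lln_v[have])
        else:
            z[have] = bccg.z_exact(observed[have], (M[have], S[have], L[have]))
        pct[have] = 100.0 * stats.norm.cdf(
            np.asarray(bccg.z_exact(observed[have], (M[have], S[have], L[have])))
        )

    out = rows[["subject_id", "sex", "age", "height"]].copy()
    out["index"] = curves.index
    out["observed"] = np.where(have, observed, np.nan)
    out["M"] = M
    out["S"] = S
    out["L"] = L
    out["LLN"] = lln_v
    out["SD"] = sd_v
    out["Z"] = z
    out["percentile"] = pct
    out["z_mode"] = z_mode
    out["extrapolated"] = ~curves.in_hull(age, height)
    return out.reset_index(drop=True)


def predict_subject(curves: LMSCurves, subject: dict | pd.Series, z_mode: str = "paper") -> dict:
    """Reference prediction for a single subject (a row-like mapping)."""
    from .synthetic import SEX_CODE

    row = dict(subject)
    row.setdefault("subject_id", "subject")
    row.setdefault("sex", SEX_CODE[curves.sex])
    df = pd.DataFrame([row])
    table = predict_table(curves, df, z_mode=z_mode)
    if table.empty:
        raise DomainError(f"subject sex does not match model sex {curves.sex!r}")
    return table.iloc[0].to_dict()


def lookup_table(curves: LMSCurves, age_grid=None, height_grid=None) -> pd.DataFrame:
    """Reference lookup table: one row per (age[, height]) with M, S, L, LLN.

    Defaults: ages 4-82 by 1 year; heights in sex-specific 5 cm steps.  For
    age-only models (no height term) the height column is NaN and the grid
    collapses to ages.
    """
    if age_grid is None:
        lo, hi = curves.age_range
        age_grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    age_grid = np.asarray(age_grid, float)
    if age_grid.size == 0:
        raise ConfigurationError("age grid is empty")

    if curves.b is None:
        heights = np.array([np.nan])
    else:
        if height_grid is None:
            if curves.height_range is not None:
                lo, hi = curves.height_range
            else:
                lo, hi = (110.0, 190.0) if curves.sex == "male" else (105.0, 180.0)
            height_grid = np.arange(5 * np.ceil(lo / 5), 5 * np.floor(hi / 5) + 1, 5.0)
        heights = np.asarray(height_grid, float)
        if heights.size == 0:
            raise ConfigurationError("height grid is empty")

    A, H = np.meshgrid(age_grid, heights, indexing="ij")
    a, h = A.ravel(), H.ravel()
    M, S, L = curves.lms_at(a, h if curves.b is not None else None)
    table = pd.DataFrame(
        {
            "index": curves.index,
            "sex": curves.sex,
            "age": a,
            "height": h,
            "M": M,
            "S": S,
            "L": L,
            "LLN": np.asarray(lln((M, S, L))),
        }
    )
    return table
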