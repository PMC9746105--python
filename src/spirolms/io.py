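"""Readers and writers: cohort CSV, model YAML, selection tables.

Cohort CSV contract: header ``subject_id,sex,age,height,weight,fev1,fvc,
fev1_fvc,fef2575``, sex coded M/F (male/female aliases accepted), height in
cm (metres auto-detected when all values < 3 and converted with a warning),
volumes in litres, UTF-8, '\\n' newlines.  Rows with non-positive age or
height are rejected and counted; per-index missing values are preserved.

Model YAML: one document per model set, each curve a mapping of the LMS
coefficients plus spline (knots, values) blocks; fitted models add a
``fit`` metadata block (n_obs, loglik, AIC, SBC, df per curve).  External
reference models (e.g. user-supplied Caucasian GLI-style coefficients) use
the same format with ``external: true`` and evaluate identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .fitting import FittedLMS, ModelSpec
from .model import INDICES, LMSCurves
from .synthetic import COHORT_COLUMNS, TrueLMSModel

__all__ = [
    "read_cohort",
    "write_cohort",
    "save_models",
    "load_models",
    "save_fit",
    "load_fit",
    "RejectionLog",
]

log = logging.getLogger(__name__)

_SEX_ALIASES = {
    "m": "M", "male": "M", "M": "M",
    "f": "F", "female": "F", "F": "F",
}
_MANDATORY = ["subject_id", "sex", "age", "height"]


@dataclass
class RejectionLog:
    n_read: int
    n_kept: int
    reasons: dict


def write_cohort(df: pd.DataFrame, path) -> None:
    df[COHORT_COLUMNS].to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_cohort(path, rejection_log: bool = False):
    """Read and validate a cohort CSV; returns the table (and optionally the log)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise InputError(f"cohort file {path} is missing mandatory columns: {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        log.warning("cohort file %s: ignoring unknown columns %s", path, unknown)
        df = df.drop(columns=unknown)
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    n_read = len(df)
    reasons: dict[str, int] = {}

    sex = df["sex"].astype(str).str.strip().str.lower().map(
        {k.lower(): v for k, v in _SEX_ALIASES.items()}
    )
    bad_sex = sex.isna()
    if bad_sex.any():
        reasons["unrecognised sex code"] = int(bad_sex.sum())
    df["sex"] = sex

    for col in ["age", "height", "weight"] + list(INDICES):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    heights = df["height"]
    finite_h = heights.dropna()
    if len(finite_h) and (finite_h < 3.0).all():
        log.warning("cohort file %s: heights look like metres; converting to cm", path)
        df["height"] = heights * 100.0

    bad_age = ~(df["age"] > 0)
    bad_height = ~(df["height"] > 0)
    if bad_age.any():
        reasons["non-positive or missing age"] = int(bad_age.sum())
    if bad_height.any():
        reasons["non-positive or missing height"] = int(bad_height.sum())

    keep = ~(bad_sex | bad_age | bad_height)
    kept = df.loc[keep, COHORT_COLUMNS].reset_index(drop=True)
    if (~keep).any():
        log.info("cohort file %s: rejected %d of %d rows (%s)", path, int((~keep).sum()), n_read, reasons)
    logrec = RejectionLog(n_read=n_read, n_kept=len(kept), reasons=reasons)
    return (kept, logrec) if rejection_log else kept


# ---------------------------------------------------------------------------
# Model YAML
# ---------------------------------------------------------------------------

def save_models(models: TrueLMSModel, path) -> None:
    """Write a model set (truth or external reference) to YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(models.to_dict(), fh, sort_keys=False)


def load_models(path) -> TrueLMSModel:
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict) or "curves" not in d:
        raise InputError(f"{path} is not a model-set YAML (no 'curves' block)")
    return TrueLMSModel.from_dict(d)


def save_fit(fit: FittedLMS, path) -> None:
    """Write one fitted model (curves + fit metadata) to YAML; round-trips losslessly."""
    d = fit.curves.to_dict()
    d["fit"] = {
        "n_obs": int(fit.n_obs),
        "n_dropped": int(fit.n_dropped),
        "loglik": float(fit.loglik),
        "edf": int(fit.edf),
        "aic": float(fit.aic),
        "sbc": float(fit.sbc),
        "converged": bool(fit.converged),
        "max_truncation_mass": float(fit.max_truncation_mass),
        "spec": {
            "index": fit.spec.index,
            "sex": fit.spec.sex,
            "df_m": fit.spec.df_m,
            "df_s": fit.spec.df_s,
            "df_l": fit.spec.df_l,
            "use_height": fit.spec.use_height,
            "sigma_log_age": fit.spec.sigma_log_age,
            "criterion": fit.spec.criterion,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_fit(path) -> FittedLMS:
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if "fit" not in d:
        raise InputError(f"{path} has no 'fit' block; use load_models for model sets")
    meta = d.pop("fit")
    curves = LMSCurves.from_dict(d)
    spec = ModelSpec(**meta["spec"])
    return FittedLMS(
        spec=spec,
        curves=curves,
        n_obs=meta["n_obs"],
        n_dropped=meta.get("n_dropped", 0),
        loglik=meta["loglik"],
        edf=meta["edf"],
        aic=meta["aic"],
        sbc=meta["sbc"],
        converged=meta["converged"],
        max_truncation_mass=meta.get("max_truncation_mass", 0.0),
        loglik_trace=[],
    )
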