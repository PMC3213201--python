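"""Sex-specific Framingham Risk Score computation.

The score is the Cox-model linear predictor for 10-year general
cardiovascular disease risk: a sex-specific weighted sum of ln(age),
ln(total cholesterol), ln(HDL), ln(SBP) — with distinct SBP weights for
treated and untreated hypertension — plus indicator terms for current
smoking and diabetes. Default coefficients are the published
Framingham general-CVD weights. The analysis phenotype downstream is
this linear predictor (or its log transform); conversion to a 10-year
probability 1 - S0^exp(LP - LPbar) is available only when the
baseline-survival constants S0 and the cohort-mean linear predictor
LPbar are supplied, since they are cohort-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PREDICTOR_COLUMNS = [
    "sex", "age", "total_chol", "hdl", "sbp", "bp_treated", "smoker", "diabetic",
]


@dataclass(frozen=True)
class SexCoefficients:
    log_age: float
    log_total_chol: float
    log_hdl: float
    log_sbp_untreated: float
    log_sbp_treated: float
    smoking: float
    diabetes: float


@dataclass(frozen=True)
class FrsCoefficients:
    """Per-sex risk-score weights; defaults are the published
    Framingham general-CVD coefficients."""

    men: SexCoefficients = field(
        default_factory=lambda: SexCoefficients(
            log_age=3.06117,
            log_total_chol=1.1237,
            log_hdl=-0.93263,
            log_sbp_untreated=1.933303,
            log_sbp_treated=1.99881,
            smoking=0.65451,
            diabetes=0.57367,
        )
    )
    women: SexCoefficients = field(
        default_factory=lambda: SexCoefficients(
            log_age=2.32888,
            log_total_chol=1.20904,
            log_hdl=-0.70833,
            log_sbp_untreated=2.76157,
            log_sbp_treated=2.82263,
            smoking=0.52873,
            diabetes=0.69154,
        )
    )

    def for_sex(self, sex: str) -> SexCoefficients:
        if sex == "male":
            return self.men
        if sex == "female":
            return self.women
        raise ValueError(f"unknown sex {sex!r}")


DEFAULT_COEFFICIENTS = FrsCoefficients()


def compute_frs(
    covariates: pd.DataFrame,
    coefs: FrsCoefficients = DEFAULT_COEFFICIENTS,
    s0: dict[str, float] | None = None,
    lp_mean: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Linear predictor (and optional 10-year risk) per subject.

    Requires columns sex, age, total_chol, hdl, sbp, bp_treated,
    smoker, diabetic. Exactly one SBP coefficient — treated or
    untreated — applies per subject. Returns a frame with sample_id,
    linear_predictor, and ten_year_risk when both ``s0`` (baseline
    survival, keyed "male"/"female") and ``lp_mean`` (cohort-mean
    linear predictor) are given.

    Raises on non-positive continuous predictors or unknown sex.
    """
    df = covariates
    for col in PREDICTOR_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"covariate table lacks column {col!r}")
    sex = df["sex"].to_numpy()
    bad_sex = ~np.isin(sex, ("male", "female"))
    if bad_sex.any():
        raise ValueError(f"unknown sex values: {set(sex[bad_sex])}")
    for col in ("age", "total_chol", "hdl", "sbp"):
        vals = df[col].to_numpy(dtype=float)
        if (vals <= 0).any() or np.isnan(vals).any():
            raise ValueError(f"{col} must be strictly positive and non-missing")
    for col in ("bp_treated", "smoker", "diabetic"):
        if not np.isin(df[col].to_numpy(), (0, 1)).all():
            raise ValueError(f"{col} must be 0/1")

    is_male = sex == "male"

    def pick(attr: str) -> np.ndarray:
        return np.where(
            is_male, getattr(coefs.men, attr), getattr(coefs.women, attr)
        )

    treated = df["bp_treated"].to_numpy() == 1
    beta_sbp = np.where(treated, pick("log_sbp_treated"), pick("log_sbp_untreated"))
    lp = (
        pick("log_age") * np.log(df["age"].to_numpy(dtype=float))
        + pick("log_total_chol") * np.log(df["total_chol"].to_numpy(dtype=float))
        + pick("log_hdl") * np.log(df["hdl"].to_numpy(dtype=float))
        + beta_sbp * np.log(df["sbp"].to_numpy(dtype=float))
        + pick("smoking") * df["smoker"].to_numpy(dtype=float)
        + pick("diabetes") * df["diabetic"].to_numpy(dtype=float)
    )
    out = pd.DataFrame(
        {"sample_id": df["sample_id"].to_numpy(), "linear_predictor": lp}
    )
    if "hdl_imputed" in df.columns:
        out["hdl_imputed"] = df["hdl_imputed"].to_numpy()
    if s0 is not None and lp_mean is not None:
        s0_vec = np.where(is_male, s0["male"], s0["female"])
        lpbar = np.where(is_male, lp_mean["male"], lp_mean["female"])
        out["ten_year_risk"] = 1.0 - s0_vec ** np.exp(lp - lpbar)
    return out


def log_transform_scores(lp: np.ndarray) -> tuple[np.ndarray, dict]:
    """Logarithm of the score, guarding non-positive values.

    Uses ln(LP) when every linear predictor is positive; otherwise
    shifts by ``1 - min(LP)`` first so the argument is >= 1. The applied
    shift is returned as metadata so the transform is reproducible.
    """
    lp = np.asarray(lp, dtype=float)
    if (lp > 0).all():
        return np.log(lp), {"shift": 0.0}
    shift = 1.0 - lp.min()
    return np.log(lp + shift), {"shift": float(shift)}


def impute_hdl_cohort_mean(
    cohort: pd.DataFrame, donor_exam_values: np.ndarray
) -> pd.DataFrame:
    """Fill missing HDL with the mean of a donor exam's values.

    Mirrors the original-cohort rule where HDL was unmeasured at the
    baseline exam and the mean from a later exam was substituted.
    Adds/updates an ``hdl_imputed`` flag column.
    """
    donors = np.asarray(donor_exam_values, dtype=float)
    donors = donors[~np.isnan(donors)]
    if donors.size == 0:
        raise ValueError("donor HDL vector is empty")
    out = cohort.copy()
    missing = out["hdl"].isna()
    out.loc[missing, "hdl"] = donors.mean()
    out["hdl_imputed"] = missing.to_numpy()
    return out


def diabetes_from_glucose(
    treated_flag: int | np.ndarray, glucose_mg_dl: float | np.ndarray
) -> int | np.ndarray:
    """Definite diabetes: treated, or blood sugar >= 200 mg/dL."""
    treated = np.asarray(treated_flag, dtype=float)
    glucose = np.asarray(glucose_mg_dl, dtype=float)
    result = ((treated == 1) | (glucose >= 200.0)).astype(int)
    return result if result.ndim else int(result)


def eligible_subjects(covariates: pd.DataFrame) -> set[str]:
    """Sample ids with complete predictor information.

    Run after :func:`impute_hdl_cohort_mean` so original-cohort subjects
    whose HDL was mean-imputed still qualify.
    """
    needed = [c for c in PREDICTOR_COLUMNS if c in covariates.columns]
    missing_any = covariates[needed].isna().any(axis=1)
    bad_sex = ~covariates["sex"].isin(["male", "female"])
    return set(covariates.loc[~(missing_any | bad_sex), "sample_id"])
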