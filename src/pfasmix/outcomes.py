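"""Cardiometabolic outcome derivation: MetS classification and the
continuous cardiometabolic risk score (CMRS).

MetS is positive when at least 3 of 5 criteria hold:

1. waist circumference >= 102 cm (males) / 88 cm (females), lowered to
   90 / 80 cm for participants of Asian ethnicity;
2. triglycerides >= 1.7 mmol/L, or lipid-lowering medication;
3. HDL-C < 1.0 mmol/L (males) / 1.3 mmol/L (females), or lipid-lowering
   medication;
4. SBP >= 130 and/or DBP >= 85 mmHg, or antihypertensive medication, or a
   prior hypertension diagnosis;
5. HbA1c >= 5.7%, or diabetes medication, or a prior type 2 diabetes
   diagnosis.  (HbA1c substitutes fasting glucose because survey blood
   draws are non-fasting; an auxiliary non-fasting glucose >= 5.6 mmol/L
   variant is available for prevalence-comparability checks.)

The CMRS aggregates age- and sex-standardized residual Z-scores of the five
risk factors, HDL entering with negative sign for its protective effect,
and mean arterial pressure combining the two BP Z-scores:

    zMAP = zDBP + (1/3)(zSBP - zDBP)
    CMRS = (zWC + zHbA1c + zTG - zHDL + zMAP) / sqrt(5)

Z-scores come from (survey-weighted) linear regressions of each
UNTRANSFORMED risk factor on age (linear) and sex, residuals scaled to
weighted SD 1.  log2 applies only when a risk factor is itself a model
outcome, never inside the CMRS.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "load_thresholds",
    "classify_mets",
    "standardize_cmrf",
    "CMRFStandardizer",
    "compute_cmrs",
    "derive_outcomes",
    "back_transform_percent",
    "percent_to_beta",
    "CMRS_COMPONENTS",
]

CMRS_COMPONENTS = ("wc", "hba1c", "tg", "hdl", "sbp", "dbp")

_REQUIRED = [
    "sex",
    "asian_flag",
    "wc",
    "tg",
    "hdl",
    "sbp",
    "dbp",
    "hba1c",
    "med_lipid",
    "med_bp",
    "med_diabetes",
    "dx_hypertension",
    "dx_t2d",
]


def load_thresholds() -> dict:
    """Load the shipped, versioned MetS threshold registry."""
    ref = importlib.resources.files("pfasmix.data").joinpath("mets_thresholds.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def classify_mets(
    records: pd.DataFrame,
    thresholds: dict | None = None,
    glycemia: str = "hba1c",
) -> pd.DataFrame:
    """Apply the five MetS criteria; returns the per-criterion booleans,
    the criterion count, and the MetS indicator (count >= 3).

    ``glycemia`` selects the glycemia criterion measure: ``"hba1c"``
    (primary) or ``"glu"`` (non-fasting glucose, comparability check).
    Missing inputs raise — records with missing data must be excluded
    upstream (complete-case), never silently classified.
    """
    thr = thresholds or load_thresholds()
    required = list(_REQUIRED)
    if glycemia == "glu":
        required.append("glu")
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        raise KeyError(f"missing columns for MetS classification: {missing_cols}")
    sub = records[required]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(
            f"missing values in MetS inputs {bad}; exclude incomplete records upstream"
        )

    male = records["sex"].astype(str).str.lower().eq("male").to_numpy()
    asian = records["asian_flag"].astype(bool).to_numpy()
    wc_thr = np.where(
        asian,
        np.where(male, thr["wc"]["asian_male"], thr["wc"]["asian_female"]),
        np.where(male, thr["wc"]["male"], thr["wc"]["female"]),
    )
    hdl_thr = np.where(male, thr["hdl"]["male"], thr["hdl"]["female"])

    med_lipid = records["med_lipid"].astype(bool).to_numpy()
    wc_high = records["wc"].to_numpy(dtype=float) >= wc_thr
    tg_high = (records["tg"].to_numpy(dtype=float) >= thr["tg"]) | med_lipid
    hdl_low = (records["hdl"].to_numpy(dtype=float) < hdl_thr) | med_lipid
    bp_high = (
        (records["sbp"].to_numpy(dtype=float) >= thr["sbp"])
        | (records["dbp"].to_numpy(dtype=float) >= thr["dbp"])
        | records["med_bp"].astype(bool).to_numpy()
        | records["dx_hypertension"].astype(bool).to_numpy()
    )
    if glycemia == "hba1c":
        glyc_meas = records["hba1c"].to_numpy(dtype=float) >= thr["hba1c"]
    elif glycemia == "glu":
        glyc_meas = records["glu"].to_numpy(dtype=float) >= thr["glu"]
    else:
        raise ValueError(f"unknown glycemia criterion {glycemia!r}")
    glyc_high = (
        glyc_meas
        | records["med_diabetes"].astype(bool).to_numpy()
        | records["dx_t2d"].astype(bool).to_numpy()
    )

    out = pd.DataFrame(
        {
            "wc_high": wc_high,
            "tg_high": tg_high,
            "hdl_low": hdl_low,
            "bp_high": bp_high,
            "glyc_high": glyc_high,
        },
        index=records.index,
    )
    out["criteria_count"] = out.sum(axis=1).astype(int)
    out["mets"] = out["criteria_count"] >= int(thr.get("n_criteria_required", 3))
    return out


def standardize_cmrf(values, age, sex, weights=None) -> np.ndarray:
    """Age- and sex-standardized residual Z-scores of one risk factor.

    Fits a (survey-weighted) linear regression of the risk factor on age
    (linear term) and sex, and returns residuals scaled so the weighted
    mean is 0 and the weighted SD is 1.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    if n < 50:
        raise ValueError(f"standardization needs n >= 50, got {n}")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing values in risk factor; complete cases required")
    age = np.asarray(age, dtype=float)
    sex_f = (
        pd.Series(sex).astype(str).str.lower().eq("female").to_numpy(dtype=float)
    )
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    X = np.column_stack([np.ones(n), age, sex_f])
    sw = np.sqrt(w)
    # least squares tolerates a single-sex stratum (constant dummy)
    beta = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
    resid = y - X @ beta
    var = np.average(resid**2, weights=w)
    y_var = np.average((y - np.average(y, weights=w)) ** 2, weights=w)
    if not np.isfinite(var) or var <= 1e-10 * max(y_var, 1e-300):
        raise ValueError("zero residual variance: Z-scores undefined")
    return resid / np.sqrt(var)


class CMRFStandardizer(BaseEstimator, TransformerMixin):
    """Transformer producing the six component Z-scores (wc, hba1c, tg,
    hdl, sbp, dbp) from a cohort frame.  ``weighted=True`` uses the survey
    weight column; a config switch to unweighted is provided.
    """

    def __init__(self, weighted: bool = True, weight_col: str = "weight"):
        self.weighted = weighted
        self.weight_col = weight_col

    def fit(self, X: pd.DataFrame, y=None):
        self.components_ = list(CMRS_COMPONENTS)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        w = X[self.weight_col].to_numpy(dtype=float) if self.weighted else None
        z = {
            f"z_{c}": standardize_cmrf(X[c], X["age"], X["sex"], w)
            for c in CMRS_COMPONENTS
        }
        return pd.DataFrame(z, index=X.index)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def compute_cmrs(z: pd.DataFrame) -> pd.Series:
    """CMRS from component Z-scores (columns z_wc, z_hba1c, z_tg, z_hdl,
    z_sbp, z_dbp).  zMAP is formed internally; HDL enters negatively;
    the sum is scaled by sqrt(5) to preserve the Z-score distribution.
    """
    need = [f"z_{c}" for c in CMRS_COMPONENTS]
    missing = [c for c in need if c not in z.columns]
    if missing:
        raise KeyError(f"missing Z-score columns: {missing}")
    z_map = z["z_dbp"] + (z["z_sbp"] - z["z_dbp"]) / 3.0
    cmrs = (z["z_wc"] + z["z_hba1c"] + z["z_tg"] - z["z_hdl"] + z_map) / np.sqrt(5.0)
    return cmrs.rename("cmrs")


def back_transform_percent(beta: float) -> float:
    """Percent difference implied by a log2-scale coefficient: (2^b - 1)*100."""
    return float((2.0 ** np.asarray(beta, dtype=float) - 1.0) * 100.0)


def percent_to_beta(percent: float) -> float:
    """Inverse of :func:`back_transform_percent`."""
    return float(np.log2(1.0 + np.asarray(percent, dtype=float) / 100.0))


def derive_outcomes(
    cohort: pd.DataFrame, weighted: bool = True, glycemia: str = "hba1c"
) -> pd.DataFrame:
    """Attach MetS criteria, Z-scores, and CMRS to a cohort table."""
    crit = classify_mets(cohort, glycemia=glycemia)
    z = CMRFStandardizer(weighted=weighted).fit_transform(cohort)
    out = pd.concat([cohort, crit, z], axis=1)
    out["cmrs"] = compute_cmrs(z)
    return out
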