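"""Model battery driver: exclusions, adjustment sets, strata, engines.

For each stratum (total, males, females) and each outcome the battery runs
one mixture (qgcomp) model, one model per individual analyte (log2
exposure), and one total-PFAS (log2 sum) model.  The medication-excluded
variant is the DEFAULT analysis for the medication-linked risk factors
(TG/HDL, SBP/DBP, GLU/HbA1c) and the everyone-included variant is always
emitted as the named sensitivity complement, so both readings of the
analysis are available.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PFAS_NAMES
from .design_matrix import build_design
from .exposures import log2_transform
from .outcomes import back_transform_percent, derive_outcomes
from .qgcomp import QGComp, summarize_mixture
from .survey import SurveyDesign, SurveyWeightedGLM

__all__ = [
    "ModelSpec",
    "build_adjustment_set",
    "apply_exclusions",
    "run_battery",
    "DEFAULT_OUTCOMES",
]

logger = logging.getLogger(__name__)

# MetS + CMRS + six risk factors; non-fasting glucose is auxiliary (opt-in)
DEFAULT_OUTCOMES = ("mets", "cmrs", "wc", "tg", "hdl", "sbp", "dbp", "hba1c")
STRATA = ("total", "males", "females")

BASE_COVARIATES = [
    "age",
    "ethnicity",
    "education",
    "smoking",
    "marital",
    "country_of_birth",
    "mvpa_min_per_day",
    "fish_meals_per_month",
    "survey_cycle",
]

# outcome -> medication flag whose users are excluded in the primary analysis
MED_EXCLUSION = {
    "tg": "med_lipid",
    "hdl": "med_lipid",
    "sbp": "med_bp",
    "dbp": "med_bp",
    "glu": "med_diabetes",
    "hba1c": "med_diabetes",
}

_LOG2_OUTCOMES = ("wc", "tg", "hdl", "sbp", "dbp", "hba1c", "glu")


@dataclass
class ModelSpec:
    """One unit of work: outcome x engine x stratum x variant."""

    outcome: str
    engine: str  # "qgcomp" | "single" | "sum"
    stratum: str = "total"
    analyte: str | None = None  # for engine="single"
    exclude_medicated: bool = True
    q: int = 4

    @property
    def family(self) -> str:
        return "poisson" if self.outcome == "mets" else "gaussian"

    @property
    def log2_outcome(self) -> bool:
        return self.outcome in _LOG2_OUTCOMES

    @property
    def estimate_type(self) -> str:
        if self.outcome == "mets":
            return "pr"
        return "percent" if self.log2_outcome else "difference"

    def model_id(self) -> str:
        parts = [self.outcome, self.engine]
        if self.analyte:
            parts.append(self.analyte)
        parts.append(self.stratum)
        parts.append("medexcl" if self._med_flag() and self.exclude_medicated else "all")
        return ":".join(parts)

    def _med_flag(self):
        return MED_EXCLUSION.get(self.outcome)


def build_adjustment_set(spec: ModelSpec) -> list[str]:
    """Covariate list per the adjustment rules.

    Base set + sex for total-population models; female-only models add
    parity and drop sex; male-only drop sex; CMRS models drop age (and
    sex) in every stratum because age/sex are already standardized out.
    """
    cov = list(BASE_COVARIATES)
    if spec.stratum == "total":
        cov.append("sex")
    elif spec.stratum == "females":
        cov.append("parity")
    elif spec.stratum != "males":
        raise ValueError(f"unknown stratum {spec.stratum!r}")
    if spec.outcome == "cmrs":
        cov = [c for c in cov if c not in ("age", "sex")]
    return cov


def apply_exclusions(
    cohort: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, dict]:
    """Drop pregnant and type-1-diabetes participants always; additionally
    drop the relevant medication users for medication-linked outcomes when
    the spec asks for the medication-excluded variant.

    The audit counts each rule's matches separately plus the deduplicated
    total, so rows(subset) + unique_dropped == rows(input).
    """
    rules = {"pregnant": cohort["pregnant"].astype(bool)}
    rules["t1d"] = cohort["t1d"].astype(bool)
    med_flag = spec._med_flag()
    if med_flag and spec.exclude_medicated:
        rules[med_flag] = cohort[med_flag].astype(bool)
    drop = np.zeros(len(cohort), dtype=bool)
    audit = {}
    for name, mask in rules.items():
        audit[f"dropped_{name}"] = int(mask.sum())
        drop |= mask.to_numpy()
    audit["dropped_unique"] = int(drop.sum())
    audit["n_input"] = int(len(cohort))
    audit["n_retained"] = int(len(cohort) - drop.sum())
    return cohort.loc[~drop], audit


def _stratum_mask(data: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "total":
        return np.ones(len(data), dtype=bool)
    if stratum in ("males", "females"):
        return data["sex"].astype(str).eq(stratum[:-1]).to_numpy()
    raise ValueError(f"unknown stratum {stratum!r}")


def _fit_one(spec: ModelSpec, data: pd.DataFrame, design: SurveyDesign) -> dict:
    cov_names = build_adjustment_set(spec)
    if spec.stratum == "females" and "parity" in cov_names and (
        "parity" not in data.columns or (data["parity"] == "").all()
    ):
        raise ValueError("configuration error: covariate 'parity' missing for the female stratum")

    model_cols = cov_names + [spec.outcome] + list(PFAS_NAMES)
    sub = data
    cc = ~sub[model_cols].isna().any(axis=1)
    if spec.stratum == "females":
        cc &= sub["parity"].astype(str) != ""
    n_dropped_cc = int((~cc).sum())
    sub = sub.loc[cc]
    des = design.subset(cc.to_numpy())

    y = sub[spec.outcome].to_numpy(dtype=float)
    if spec.log2_outcome:
        y = np.asarray(log2_transform(y))
    cov = build_design(sub, cov_names, add_intercept=False)

    row = {
        "model_id": spec.model_id(),
        "outcome": spec.outcome,
        "engine": spec.engine,
        "analyte": spec.analyte or "",
        "stratum": spec.stratum,
        "variant": "medication-excluded"
        if (spec._med_flag() and spec.exclude_medicated)
        else "all-participants",
        "estimate_type": spec.estimate_type,
        "n": int(len(sub)),
        "n_dropped_incomplete": n_dropped_cc,
        "n_replicates": des.n_replicates,
    }

    if spec.engine == "qgcomp":
        fit = QGComp(q=spec.q, family=spec.family).fit(
            sub[list(PFAS_NAMES)], y, covariates=cov, design=des
        )
        summ = summarize_mixture(fit, spec.estimate_type)
        row.update(
            link_estimate=summ["psi"],
            se=summ["se"],
            estimate=summ["estimate"],
            ci_lower=summ["ci_lower"],
            ci_upper=summ["ci_upper"],
        )
        for a in PFAS_NAMES:
            row[f"w_pos_{a}"] = fit.weights_positive_.get(a, np.nan)
            row[f"w_neg_{a}"] = fit.weights_negative_.get(a, np.nan)
        return row

    if spec.engine == "single":
        expo = np.asarray(log2_transform(sub[spec.analyte].to_numpy(dtype=float)))
        term = f"log2_{spec.analyte}"
    elif spec.engine == "sum":
        expo = np.asarray(log2_transform(sub[list(PFAS_NAMES)].sum(axis=1).to_numpy()))
        term = "log2_sum_pfas"
    else:
        raise ValueError(f"unknown engine {spec.engine!r}")
    X = cov.copy()
    X.insert(0, term, expo)
    X.insert(0, "(Intercept)", 1.0)
    glm = SurveyWeightedGLM(family=spec.family).fit(X, y, design=des)
    j = glm.term_names_.index(term)
    b, lo, hi = glm.coef_[j], glm.ci_lower_[j], glm.ci_upper_[j]
    if spec.estimate_type == "pr":
        est, lo_t, hi_t = np.exp(b), np.exp(lo), np.exp(hi)
    elif spec.estimate_type == "percent":
        est, lo_t, hi_t = (
            back_transform_percent(b),
            back_transform_percent(lo),
            back_transform_percent(hi),
        )
    else:
        est, lo_t, hi_t = b, lo, hi
    row.update(
        link_estimate=float(b),
        se=float(glm.se_[j]),
        estimate=float(est),
        ci_lower=float(lo_t),
        ci_upper=float(hi_t),
    )
    for a in PFAS_NAMES:
        row[f"w_pos_{a}"] = np.nan
        row[f"w_neg_{a}"] = np.nan
    return row


def run_battery(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    outcomes=DEFAULT_OUTCOMES,
    strata=STRATA,
    q: int = 4,
    include_sensitivity: bool = True,
    weighted_standardization: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the full model battery; returns (tidy results, metadata).

    The cohort must contain imputed exposures (no masked non-detects).
    MetS and CMRS are derived on the analytic sample (after the universal
    pregnancy/T1D exclusions) before model-specific subsetting.  Failures
    are recorded and skipped, never silently dropped.
    """
    # universal rules only: the cmrs/sum spec carries no medication exclusion
    analytic, audit = apply_exclusions(cohort, ModelSpec("cmrs", "sum"))
    des = design.subset(cohort.index.isin(analytic.index))
    analytic = derive_outcomes(analytic, weighted=weighted_standardization)
    analytic["mets"] = analytic["mets"].astype(float)

    rows, failures, audits = [], [], {"universal": audit}
    t0 = time.time()
    for stratum in strata:
        mask = _stratum_mask(analytic, stratum)
        strat_data = analytic.loc[mask]
        strat_des = des.subset(mask)
        for outcome in outcomes:
            variants = [True]
            if include_sensitivity and outcome in MED_EXCLUSION:
                variants = [True, False]
            for excl in variants:
                specs = [
                    ModelSpec(outcome, "qgcomp", stratum, None, excl, q),
                    *[
                        ModelSpec(outcome, "single", stratum, a, excl, q)
                        for a in PFAS_NAMES
                    ],
                    ModelSpec(outcome, "sum", stratum, None, excl, q),
                ]
                for spec in specs:
                    med_flag = spec._med_flag()
                    if med_flag and spec.exclude_medicated:
                        data, a2 = _subset_medication(strat_data, med_flag)
                        d2 = strat_des.subset(
                            ~strat_data[med_flag].astype(bool).to_numpy()
                        )
                        audits[spec.model_id()] = a2
                    else:
                        data, d2 = strat_data, strat_des
                    try:
                        row = _fit_one(spec, data, d2)
                        row["primary"] = excl or outcome not in MED_EXCLUSION
                        rows.append(row)
                        logger.info(
                            "fit %s: n=%d", spec.model_id(), row["n"]
                        )
                    except Exception as exc:  # noqa: BLE001 - recorded, not hidden
                        failures.append({"model_id": spec.model_id(), "error": str(exc)})
                        logger.error("model %s failed: %s", spec.model_id(), exc)
    logger.info("battery wall time %.1fs", time.time() - t0)
    results = pd.DataFrame(rows)
    meta = {
        "n_models": len(rows),
        "n_failures": len(failures),
        "failures": failures,
        "audit": audits,
        "outcomes": list(outcomes),
        "strata": list(strata),
        "q": q,
        "n_replicates": design.n_replicates,
        "qgcomp_variant": "conditional-sum-of-coefficients",
    }
    return results, meta


def _subset_medication(data: pd.DataFrame, med_flag: str):
    mask = ~data[med_flag].astype(bool)
    audit = {
        f"dropped_{med_flag}": int((~mask).sum()),
        "n_input": int(len(data)),
        "n_retained": int(mask.sum()),
    }
    return data.loc[mask], audit


def write_results(results: pd.DataFrame, meta: dict, outdir, stem: str = "results"):
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.to_csv(outdir / f"{stem}.csv", index=False)
    with open(outdir / f"{stem}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
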