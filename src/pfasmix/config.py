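"""Cohort-generator configuration: the study conditions the synthetic
population emulates.

Defaults mirror the descriptive profile of the adult (20-79) survey
population the package targets: five correlated lognormal plasma PFAS with
sex-specific geometric means (e.g. PFOS 5.2 vs 3.2 ug/L, PFHxS 1.6 vs 0.8
ug/L for males vs females), pairwise Spearman correlations in the 0.3-0.8
range, ~18% non-detects for PFDA at its LOD, risk-factor means/SDs from the
survey's descriptive table, and medication-use prevalences of 20% (lipid),
21% (antihypertensive) and 7% (diabetes).  Ground-truth mixture effects
(``true_psi``, per one-quartile joint increase, on each outcome's modelling
scale) default to magnitudes comparable to the motivating analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

PFAS_NAMES = ("PFOA", "PFOS", "PFHxS", "PFDA", "PFNA")
CONTINUOUS_OUTCOMES = ("wc", "tg", "hdl", "sbp", "dbp", "hba1c", "glu")

# Spearman rank-correlation targets (moderate-to-strong, 0.3-0.8)
_DEFAULT_SPEARMAN = np.array(
    [
        # PFOA  PFOS  PFHxS PFDA  PFNA
        [1.00, 0.70, 0.60, 0.40, 0.60],
        [0.70, 1.00, 0.60, 0.50, 0.60],
        [0.60, 0.60, 1.00, 0.30, 0.40],
        [0.40, 0.50, 0.30, 1.00, 0.70],
        [0.60, 0.60, 0.40, 0.70, 1.00],
    ]
)

# target marginal means/SDs of the risk factors (units: wc cm; tg/hdl/glu
# mmol/L; sbp/dbp mmHg; hba1c %), by sex
_OUTCOME_MEANS = {
    "wc": {"male": 96.7, "female": 90.6},
    "tg": {"male": 1.48, "female": 1.23},
    "hdl": {"male": 1.29, "female": 1.58},
    "sbp": {"male": 115.0, "female": 113.0},
    "dbp": {"male": 74.0, "female": 70.0},
    "hba1c": {"male": 5.62, "female": 5.53},
    "glu": {"male": 5.58, "female": 5.25},
}
_OUTCOME_SDS = {
    "wc": {"male": 14.0, "female": 16.3},
    "tg": {"male": 0.76, "female": 0.65},
    "hdl": {"male": 0.36, "female": 0.43},
    "sbp": {"male": 14.0, "female": 17.0},
    "dbp": {"male": 9.0, "female": 11.0},
    "hba1c": {"male": 0.67, "female": 0.73},
    "glu": {"male": 1.08, "female": 1.29},
}

# ground-truth joint mixture effect per one-quartile increase in all five
# analytes, on the modelling scale (log2 for the risk factors)
_TRUE_PSI = {
    "wc": -0.0228,
    "tg": 0.0689,
    "hdl": 0.0349,
    "sbp": 0.0014,
    "dbp": -0.0176,
    "hba1c": 0.0166,
    "glu": 0.0215,
}

# per-analyte signed shares of true_psi (sum to 1 per outcome);
# PFNA-dominant for the glycemia outcomes, PFDA-weighted elsewhere
_PNA_HEAVY = (0.05, 0.35, 0.0, 0.0, 0.60)
_PFDA_HEAVY = (0.10, 0.20, 0.10, 0.50, 0.10)
_UNIFORM = (0.2, 0.2, 0.2, 0.2, 0.2)
_TRUE_WEIGHTS = {
    "wc": _PFDA_HEAVY,
    "tg": _UNIFORM,
    "hdl": _UNIFORM,
    "sbp": _UNIFORM,
    "dbp": _UNIFORM,
    "hba1c": _PNA_HEAVY,
    "glu": _PNA_HEAVY,
}

# modest covariate effects on the log2 outcome scale
_COVARIATE_EFFECTS = {
    "wc": {"age10": 0.020, "smoking_ever": 0.00, "mvpa10": -0.010},
    "tg": {"age10": 0.020, "smoking_ever": 0.03, "mvpa10": -0.015},
    "hdl": {"age10": 0.005, "smoking_ever": -0.02, "mvpa10": 0.010},
    "sbp": {"age10": 0.030, "smoking_ever": 0.01, "mvpa10": -0.005},
    "dbp": {"age10": 0.010, "smoking_ever": 0.01, "mvpa10": -0.005},
    "hba1c": {"age10": 0.025, "smoking_ever": 0.01, "mvpa10": -0.005},
    "glu": {"age10": 0.015, "smoking_ever": 0.01, "mvpa10": -0.005},
}

# covariate marginals (weighted % from the survey's descriptive table)
COVARIATE_MARGINALS = {
    "survey_cycle": {2: 0.309, 5: 0.367, 6: 0.324},
    "ethnicity": {"white": 0.765, "other": 0.235},
    "asian_fraction": 0.12,  # of the full sample, within "other"
    "education": {
        "high_school_or_less": 0.056,
        "secondary": 0.253,
        "post_secondary": 0.691,
    },
    "marital": {"married_common_law": 0.657, "widowed_sep_div": 0.090, "single": 0.253},
    "smoking": {"never": 0.808, "ever": 0.192},
    "country_of_birth": {"canada": 0.699, "foreign": 0.301},
    "parity": {"0": 0.322, "1": 0.115, "2": 0.388, "3+": 0.175},
    "age_mean": 49.8,
    "age_sd": 15.5,
    "fish_mean": 7.67,
    "fish_sd": 8.80,
    "mvpa_mean": 22.7,
    "mvpa_sd": 24.1,
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    ``noise_sd`` may be left None, in which case per-outcome residual SDs
    are derived so the marginal log-scale spread matches
    ``sd_shrink * (target SD implied by the descriptive table)``.
    """

    n_participants: int = 1071
    seed: int = 0
    sex_fraction_female: float = 0.52
    pfas_names: tuple = PFAS_NAMES
    pfas_gm_by_sex: dict = field(
        default_factory=lambda: {
            "male": {"PFOA": 2.0, "PFOS": 5.2, "PFHxS": 1.6, "PFDA": 0.20, "PFNA": 0.84},
            "female": {"PFOA": 1.6, "PFOS": 3.2, "PFHxS": 0.8, "PFDA": 0.16, "PFNA": 0.68},
        }
    )
    pfas_gsd: dict = field(
        default_factory=lambda: {
            "PFOA": 1.9, "PFOS": 2.1, "PFHxS": 2.3, "PFDA": 1.9, "PFNA": 1.9,
        }
    )
    spearman_target: np.ndarray = field(default_factory=lambda: _DEFAULT_SPEARMAN.copy())
    lod: dict = field(
        default_factory=lambda: {
            "PFOA": 0.1, "PFOS": 0.3, "PFHxS": 0.1, "PFDA": 0.1, "PFNA": 0.1,
        }
    )
    true_psi: dict = field(default_factory=lambda: dict(_TRUE_PSI))
    true_weights: dict = field(default_factory=lambda: {k: tuple(v) for k, v in _TRUE_WEIGHTS.items()})
    covariate_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in _COVARIATE_EFFECTS.items()})
    outcome_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in _OUTCOME_MEANS.items()})
    outcome_sds: dict = field(default_factory=lambda: {k: dict(v) for k, v in _OUTCOME_SDS.items()})
    noise_sd: dict | None = None
    # dependence structure among risk factors (fractions of marginal SD)
    latent_fraction: float = 0.40
    bp_factor_loading: float = 0.60
    glyc_factor_loading: float = 0.55
    # bulk lognormal spread as a fraction of the printed (outlier-inflated) SD;
    # calibrated once so the classifier-emergent MetS prevalence sits near 27%
    sd_shrink: float = 0.85
    med_prevalence: dict = field(
        default_factory=lambda: {"lipid": 0.20, "bp": 0.21, "diabetes": 0.07}
    )
    dx_prevalence: dict = field(
        default_factory=lambda: {"hypertension": 0.12, "t2d": 0.06}
    )
    med_severity_slope: float = 3.0
    pregnant_rate_young_f: float = 0.05  # among females aged < 45
    t1d_rate: float = 0.023
    n_sites: int = 16
    n_replicates: int = 500
    weight_cv: float = 0.3

    # -- validation ------------------------------------------------------

    def validate(self) -> "CohortConfig":
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 <= self.sex_fraction_female <= 1.0):
            raise ValueError("sex_fraction_female must be a proportion")
        for sex in ("male", "female"):
            for a in self.pfas_names:
                if self.pfas_gm_by_sex[sex][a] <= 0:
                    raise ValueError(f"GM for {a} ({sex}) must be > 0")
        for a in self.pfas_names:
            if self.pfas_gsd[a] <= 1.0:
                raise ValueError(f"GSD for {a} must be > 1")
            if self.lod[a] < 0:
                raise ValueError(f"LOD for {a} must be >= 0")
        R = np.asarray(self.spearman_target, dtype=float)
        k = len(self.pfas_names)
        if R.shape != (k, k):
            raise ValueError(f"spearman_target must be {k}x{k}")
        if not np.allclose(R, R.T):
            raise ValueError("spearman_target must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("spearman_target must have unit diagonal")
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise ValueError(
                f"spearman_target is not positive semidefinite "
                f"(min eigenvalue {eig.min():.3g})"
            )
        for o, shares in self.true_weights.items():
            if abs(sum(shares) - 1.0) > 1e-8:
                raise ValueError(f"true_weights for {o!r} must sum to 1")
        for p in list(self.med_prevalence.values()) + list(self.dx_prevalence.values()):
            if not (0.0 <= p <= 1.0):
                raise ValueError("prevalences must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2 for the site bootstrap")
        return self

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path):
        d = asdict(self)
        d["spearman_target"] = np.asarray(self.spearman_target).tolist()
        d["pfas_names"] = list(self.pfas_names)
        d["true_weights"] = {k: list(v) for k, v in self.true_weights.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["spearman_target"] = np.asarray(d["spearman_target"], dtype=float)
        d["pfas_names"] = tuple(d["pfas_names"])
        if "true_weights" in d:
            d["true_weights"] = {k: tuple(v) for k, v in d["true_weights"].items()}
        if "survey_cycle" in d.get("covariate_marginals", {}):  # pragma: no cover
            pass
        cfg = cls(**d)
        return cfg.validate()
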