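"""Synthetic survey cohort with known ground-truth mixture effects.

The generator emulates a national biomonitoring survey of adults aged
20-79: five correlated lognormal plasma PFAS (Gaussian copula preserving a
target Spearman matrix), sociodemographic covariates with realistic
marginals, continuous cardiometabolic risk factors driven by a linear model
on the quantized joint exposure index (so the quantile-g-computation
estimand is exactly recoverable), value-dependent medication/diagnosis
flags at configured prevalences, and a single-stratum multisite design with
Rao-Wu-Yue rescaled bootstrap replicate weights.

MetS status is never generated directly: it must emerge from applying the
clinical classifier in :mod:`pfasmix.outcomes` to the generated risk
factors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import CONTINUOUS_OUTCOMES, COVARIATE_MARGINALS, CohortConfig
from .qgcomp import quantize
from .survey import SurveyDesign

__all__ = [
    "generate_cohort",
    "censor_below_lod",
    "generate_replicate_weights",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1
_LN2 = np.log(2.0)


def spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    """Gaussian-copula conversion: rho_P = 2 sin(pi * rho_S / 6)."""
    R = 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)
    np.fill_diagonal(R, 1.0)
    return R


def _truncated_normal(rng, mean, sd, lo, hi, size):
    from scipy.special import ndtr, ndtri

    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    return mean + sd * ndtri(a + (b - a) * rng.uniform(size=size))


def _lognormal_match(rng, mean, sd, size):
    """Lognormal draws with the requested arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * rng.standard_normal(size))


def _gamma_match(rng, mean, sd, size):
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size)


def _solve_bernoulli_intercept(z, slope, target):
    """Find a so that mean(expit(a + slope*z)) == target; warn if unreachable."""

    def gap(a):
        return float(np.mean(expit(a + slope * z))) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - degenerate configs
        achieved = target + gap(0.0)
        warnings.warn(
            f"target prevalence {target:.3f} unreachable; achieved {achieved:.3f}",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return brentq(gap, lo, hi, xtol=1e-10)


def _conditional_bernoulli(rng, z, slope, target):
    """Bernoulli draws whose probability rises with severity z while the
    sample-average probability equals the configured prevalence."""
    if target <= 0:
        return np.zeros(z.shape[0], dtype=bool)
    a = _solve_bernoulli_intercept(z, slope, target)
    return rng.uniform(size=z.shape[0]) < expit(a + slope * z)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one participant table (schema version 1, uncensored PFAS).

    Reproducible: identical config + seed give an identical table.
    See docs/cohort_schema.md for the column contract.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    M = COVARIATE_MARGINALS

    # -- demographics ----------------------------------------------------
    female = rng.uniform(size=n) < cfg.sex_fraction_female
    sex = np.where(female, "female", "male")
    age = _truncated_normal(rng, M["age_mean"], M["age_sd"], 20.0, 79.0, n)

    def cat(dist):
        keys = list(dist.keys())
        probs = np.array(list(dist.values()), dtype=float)
        return rng.choice(keys, size=n, p=probs / probs.sum())

    cycle = cat(M["survey_cycle"]).astype(int)
    ethnicity = cat(M["ethnicity"])
    # Asian ethnicity is a subset of "other"
    p_other = M["ethnicity"]["other"]
    asian = (ethnicity == "other") & (
        rng.uniform(size=n) < min(M["asian_fraction"] / p_other, 1.0)
    )
    education = cat(M["education"])
    marital = cat(M["marital"])
    smoking = cat(M["smoking"])
    cob = cat(M["country_of_birth"])
    parity = np.where(female, cat(M["parity"]), "")
    fish = _lognormal_match(rng, M["fish_mean"], M["fish_sd"], n)
    mvpa = _gamma_match(rng, M["mvpa_mean"], M["mvpa_sd"], n)
    pregnant = female & (age < 45.0) & (rng.uniform(size=n) < cfg.pregnant_rate_young_f)
    t1d = rng.uniform(size=n) < cfg.t1d_rate

    # -- PFAS: Gaussian copula, lognormal marginals ----------------------
    k = len(cfg.pfas_names)
    R = spearman_to_pearson(np.asarray(cfg.spearman_target, dtype=float))
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError(
            "correlation matrix not positive semidefinite after the "
            f"rank-to-Pearson conversion (min eigenvalue {eig.min():.3g})"
        )
    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    Z = rng.standard_normal((n, k)) @ L.T
    conc = np.empty((n, k))
    for j, a in enumerate(cfg.pfas_names):
        gm = np.where(
            female, cfg.pfas_gm_by_sex["female"][a], cfg.pfas_gm_by_sex["male"][a]
        )
        conc[:, j] = np.exp(np.log(gm) + np.log(cfg.pfas_gsd[a]) * Z[:, j])
    pfas = pd.DataFrame(conc, columns=list(cfg.pfas_names))

    # -- joint exposure index (quartile scores of the true concentrations)
    qscores = quantize(pfas, q=4).scores.to_numpy(dtype=float)

    # -- risk factors on the log2 scale ----------------------------------
    latent = rng.standard_normal(n)
    bp_factor = rng.standard_normal(n)
    glyc_factor = rng.standard_normal(n)
    age10 = (age - 50.0) / 10.0
    smoking_ever = (smoking == "ever").astype(float)
    mvpa10 = mvpa / 10.0

    values = {}
    zscores = {}
    for o in CONTINUOUS_OUTCOMES:
        s_by_sex = {
            sx: cfg.sd_shrink
            * np.sqrt(np.log1p((cfg.outcome_sds[o][sx] / cfg.outcome_means[o][sx]) ** 2))
            / _LN2
            for sx in ("male", "female")
        }
        s_bar = 0.5 * (s_by_sex["male"] + s_by_sex["female"])
        lam = cfg.latent_fraction * s_bar * (-1.0 if o == "hdl" else 1.0)
        extra = np.zeros(n)
        if o in ("sbp", "dbp"):
            extra = cfg.bp_factor_loading * s_bar * bp_factor
        elif o in ("hba1c", "glu"):
            extra = cfg.glyc_factor_loading * s_bar * glyc_factor
        ce = cfg.covariate_effects.get(o, {})
        shares = np.asarray(cfg.true_weights[o], dtype=float)
        psi = float(cfg.true_psi.get(o, 0.0))
        lp = (
            lam * latent
            + extra
            + ce.get("age10", 0.0) * age10
            + ce.get("smoking_ever", 0.0) * smoking_ever
            + ce.get("mvpa10", 0.0) * mvpa10
            + psi * (qscores @ shares)
        )
        if cfg.noise_sd is not None and o in cfg.noise_sd:
            noise_sd = float(cfg.noise_sd[o])
        else:
            sys_var = float(np.var(lp))
            noise_sd = np.sqrt(max(s_bar**2 - sys_var, (0.3 * s_bar) ** 2))
        lp = lp + noise_sd * rng.standard_normal(n)
        # sex-specific intercepts matching the target arithmetic means
        log2v = np.empty(n)
        for sx, mask in (("male", ~female), ("female", female)):
            lpc = lp[mask] - lp[mask].mean()
            m = np.log2(cfg.outcome_means[o][sx]) - _LN2 * np.var(lpc) / 2.0
            log2v[mask] = m + lpc
        values[o] = 2.0**log2v
        zscores[o] = (log2v - log2v.mean()) / log2v.std()

    # -- medication / diagnosis flags (value-dependent, configured
    #    marginal prevalences) ------------------------------------------
    slope = cfg.med_severity_slope
    z_lipid = (zscores["tg"] - zscores["hdl"]) / np.sqrt(2.0)
    z_bp = (zscores["sbp"] + zscores["dbp"]) / np.sqrt(2.0)
    z_glyc = zscores["hba1c"]
    med_lipid = _conditional_bernoulli(rng, z_lipid, slope, cfg.med_prevalence["lipid"])
    med_bp = _conditional_bernoulli(rng, z_bp, slope, cfg.med_prevalence["bp"])
    med_diab = _conditional_bernoulli(
        rng, z_glyc, 2.0 * slope, cfg.med_prevalence["diabetes"]
    )
    dx_htn = _conditional_bernoulli(
        rng, z_bp, slope, cfg.dx_prevalence["hypertension"]
    )
    dx_t2d = _conditional_bernoulli(rng, z_glyc, 2.0 * slope, cfg.dx_prevalence["t2d"])

    # -- survey design ---------------------------------------------------
    site = rng.integers(0, cfg.n_sites, size=n)
    weight = _lognormal_match(rng, 1000.0, 1000.0 * cfg.weight_cv, n)

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "survey_cycle": cycle,
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "asian_flag": asian,
            "education": education,
            "marital": marital,
            "smoking": smoking,
            "country_of_birth": cob,
            "parity": parity,
            "fish_meals_per_month": fish,
            "mvpa_min_per_day": mvpa,
            "pregnant": pregnant,
            "t1d": t1d,
        }
    )
    for a in cfg.pfas_names:
        cohort[a] = pfas[a]
        cohort[f"{a}_nd"] = False
    for o in CONTINUOUS_OUTCOMES:
        cohort[o] = values[o]
    cohort["med_lipid"] = med_lipid
    cohort["med_bp"] = med_bp
    cohort["med_diabetes"] = med_diab
    cohort["dx_hypertension"] = dx_htn
    cohort["dx_t2d"] = dx_t2d
    cohort["site"] = site
    cohort["weight"] = weight
    return cohort


def censor_below_lod(cohort: pd.DataFrame, lod: dict) -> tuple[pd.DataFrame, dict]:
    """Flag concentrations below their LOD as non-detect and mask the value.

    Returns the censored table and a per-analyte detection-frequency
    report.  A zero LOD yields 100% detection; an LOD above every value
    yields 0%.
    """
    out = cohort.copy()
    report = {}
    for a, lim in lod.items():
        if np.any(np.asarray(lim) < 0):
            raise ValueError(f"LOD for {a} must be >= 0")
        vals = out[a].to_numpy(dtype=float)
        nd = vals < lim
        out[f"{a}_nd"] = nd
        out.loc[nd, a] = np.nan
        report[a] = float(1.0 - nd.mean())
    return out, report


def generate_replicate_weights(
    cohort: pd.DataFrame,
    n_replicates: int,
    seed: int,
    resample: bool = True,
    strata: np.ndarray | None = None,
) -> SurveyDesign:
    """Rao-Wu-Yue rescaled bootstrap replicate weights.

    Within each stratum the n_h first-stage sites are resampled with
    replacement n_h - 1 times per replicate; units in site i get their main
    weight multiplied by (n_h / (n_h - 1)) * r_i where r_i is the number of
    times the site was drawn.  Each replicate's total weight then matches
    the main total in expectation.  ``resample=False`` is a degenerate test
    mode where every replicate equals the main weights (replicate variance
    is exactly zero downstream).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    w = cohort["weight"].to_numpy(dtype=float)
    n = w.shape[0]
    if not resample:
        return SurveyDesign(w, np.tile(w[:, None], (1, n_replicates)))
    site = cohort["site"].to_numpy()
    strat = np.zeros(n, dtype=int) if strata is None else np.asarray(strata)
    rng = np.random.default_rng(seed)
    mult = np.ones((n, n_replicates))
    for h in np.unique(strat):
        in_h = strat == h
        sites_h = np.unique(site[in_h])
        n_h = sites_h.size
        if n_h < 2:
            raise ValueError(
                f"stratum {h!r} has {n_h} site(s); the bootstrap needs >= 2"
            )
        m = n_h - 1
        # site index within stratum for each unit
        pos = np.searchsorted(sites_h, site[in_h])
        counts = rng.multinomial(m, np.full(n_h, 1.0 / n_h), size=n_replicates)
        mult[in_h, :] = (counts.T[pos, :]) * (n_h / m)
    return SurveyDesign(w, w[:, None] * mult)


def write_cohort_csv(cohort: pd.DataFrame, path):
    """Serialize the cohort with its schema version stamped in a header
    comment-free companion: the version is carried in the column name
    contract documented in docs/cohort_schema.md."""
    cohort.to_csv(path, index=False)
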