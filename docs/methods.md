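# Methods

`pfasmix` implements a survey-weighted mixture analysis of plasma PFAS and
cardiometabolic health, together with a synthetic cohort generator that
makes every stage testable against known ground truth.  This note records
the statistical model, the defaults, the numerical choices, and what the
synthetic benchmark can and cannot show.

## Exposure processing

Nine-analyte biomonitoring panels are reduced to the analytes detected in
at least 70% of samples (boundary inclusive).  Concentrations below the
limit of detection (LOD) are treated as left-censored lognormal
observations: detected values contribute the density, non-detects the CDF
at their (possibly per-record) LOD, and the two lognormal parameters are
estimated by maximum likelihood (`scipy.stats.CensoredData` + `norm.fit`
on the log scale).  Each non-detect is then replaced by a *single* draw
from the fitted lognormal truncated to (0, LOD) — the "fill-in"
imputation, which yields unbiased downstream regression coefficients when
the imputation distribution is correct.  We deliberately use the censored
MLE rather than LOD/√2 substitution.  Imputation uses one global seed with
per-analyte substreams, so adding or removing an analyte never perturbs
the draws of the others; parameters, detection frequencies and the seed
are written to a sidecar metadata file.  Multiple imputation (with
between-imputation variance) is out of scope.

Each analyte, and the total ∑PFAS (summed on the original concentration
scale *after* imputation), is log2-transformed when it enters a
single-pollutant model, so coefficients read as the effect of each
two-fold increase in concentration.

## Outcomes

**MetS** is positive when ≥ 3 of 5 criteria hold: elevated waist
circumference (≥ 102/88 cm for males/females, 90/80 cm for Asian
ethnicity), triglycerides ≥ 1.7 mmol/L or lipid-lowering medication,
HDL-C < 1.0/1.3 mmol/L or lipid-lowering medication, blood pressure
≥ 130 systolic and/or ≥ 85 mmHg diastolic or antihypertensive medication
or a prior hypertension diagnosis, and HbA1c ≥ 5.7% or diabetes medication
or a prior type 2 diabetes diagnosis.  HbA1c replaces fasting glucose
because survey blood draws are non-fasting; a non-fasting glucose
(≥ 5.6 mmol/L) variant of the glycemia criterion is available as a
prevalence-comparability check, never as a CMRS component.  Thresholds
live in a versioned YAML registry (`pfasmix/data/mets_thresholds.yaml`) so
guideline variants can be added.  The HbA1c threshold is implemented on
the percent scale (the SI mmol/mol alternative is a unit note, not a
second threshold).

**CMRS** (continuous MetS severity) aggregates age- and sex-standardized
residual Z-scores of the five untransformed risk factors.  Each Z is the
residual from a survey-weighted linear regression of the risk factor on
age (linear) and sex, scaled to weighted SD 1 (an unweighted switch is
provided).  Blood pressure enters through the mean-arterial-pressure
Z-score, zMAP = zDBP + (zSBP − zDBP)/3, HDL-C with a negative sign for its
protective effect, and the sum is divided by √5 to preserve the Z-scale:

    CMRS = (zWC + zHbA1c + zTG − zHDL + zMAP) / √5

If the six component Zs were independent standard normal, Var(zMAP) = 5/9
and Var(CMRS) = 41/45 ≈ 0.911 — an analytic limit the test suite checks by
Monte Carlo.  Continuous risk-factor outcomes are log2-transformed in the
models and coefficients are back-transformed to percent differences via
(2^β − 1)·100; CMRS itself is analyzed untransformed.

## Estimation

**Survey-weighted GLM.**  Two families: gaussian/identity and poisson/log.
Fitting is iteratively reweighted least squares on the main weights
(deviance tolerance 1e−8, max 100 iterations; rank deficiency raises an
error naming the collinear terms).  A poisson/log fit on a 0/1 outcome is
the *modified Poisson* prevalence-ratio estimator: its variance never
comes from the model-based Poisson variance but from replicate-weight
refits or, when no replicate weights are supplied (B = 0), a robust
sandwich with the main weights.  Fitted probabilities above 1 are allowed
with a logged warning.  Complete cases are enforced upstream; NaNs raise.

**Replicate-weight variance.**  The design bootstrap resamples first-stage
sites within strata (Rao–Wu–Yue rescaling: n_h − 1 draws with replacement,
multiplier (n_h/(n_h−1))·r_i), so each replicate's weight total matches
the main total in expectation.  Variance combines as

    Var(θ̂) = (scale/B) · Σ_b (θ_b − θ̂_full)²

with scale = 1 by default (correct for this rescaling; configurable).
When a replicate weight vector zeroes out a covariate category the
replicate refit falls back to least squares — the main-fit rank check is
unaffected.  Confidence intervals are Wald on the link scale with the
1.96 normal quantile (no degrees-of-freedom correction; a t-quantile
option exists).  Replicate variance replaces, rather than combines with,
the sandwich whenever B ≥ 1.

**Quantile g-computation.**  Exposures are quantized to quartile scores
(q = 4 by default) using unweighted empirical cutpoints on the full
analytic sample; ties at a cutpoint fall in the lower bin (right-open
intervals) for bit-reproducibility.  The outcome is regressed on the
quantized exposures plus covariates, and the joint effect per
one-quantile increase in all exposures is Ψ = Σ_j β_j, with directional
weights w_j = β_j / Σ_{same sign} β_k (each direction summing to 1;
an empty direction yields an empty set, not zeros).  Cutpoints are held
fixed across replicate refits so replicate spread reflects estimation,
not binning.  This is the conditional ("sum of coefficients") estimator
for both families; for poisson/log the exponentiated Ψ is therefore a
conditional prevalence ratio, and the marginalized bootstrap variant is
intentionally not implemented — the variant is recorded in every output's
metadata.  No exposure interactions or nonlinear quantile terms are fit.

## Model battery

Strata: total, males, females (stratified models never adjust for sex).
Default outcomes: MetS (modified Poisson), CMRS (gaussian, untransformed)
and six log2 risk factors (WC, TG, HDL-C, SBP, DBP, HbA1c); non-fasting
glucose is available as an opt-in auxiliary outcome.  Engines per
outcome × stratum: one qgcomp mixture model, five single-analyte models
and one ∑PFAS model — 3 × 8 × 7 = 168 primary rows.  Covariate sets:
age, race/ethnicity, education, smoking, marital status, country of
birth, physical activity, fish/shellfish consumption and survey cycle;
total-population models add sex; female models add parity; CMRS models
drop age and sex (already standardized out).  Pregnant and
type-1-diabetes participants are always excluded; for the
medication-linked outcomes the medication-excluded subset (lipid
medication for TG/HDL, antihypertensives for SBP/DBP, diabetes medication
for GLU/HbA1c) is the *default* analysis and the everyone-included
variant is always emitted as the named sensitivity complement.  Exclusion
audits are deduplicated so retained + unique-dropped = input.  Missing
values are handled by listwise deletion per model with logged counts.  No
multiplicity adjustment is applied; significance flags are annotations
only.  Model failures are recorded and skipped, never silently dropped.

## Synthetic cohort

The generator emulates a national health-measures survey of adults 20–79:

* **PFAS**: Gaussian copula with the exact rank-to-Pearson conversion
  ρ_P = 2·sin(πρ_S/6) and lognormal marginals; sex-specific geometric
  means (PFOS 5.2 vs 3.2 µg/L, PFHxS 1.6 vs 0.8 µg/L, …), GSDs ≈ 1.9–2.3,
  Spearman targets 0.3–0.7.  The copula contract is conditional on sex;
  sex-specific means add a little extra marginal correlation, keeping the
  full-sample range at 0.3–0.8.  The default PFDA LOD (0.1 µg/L) yields
  ≈ 82% detection; the other analytes are detected in > 95%.
* **Risk factors** are generated on the log2 scale from a linear model:
  sex-specific intercept + age trend + a shared "metabolic" latent factor
  (loading 0.40 of the marginal SD, negative for HDL) + blood-pressure and
  glycemia-specific factors (0.60/0.55) + small lifestyle-covariate
  effects + the ground-truth mixture term Ψ_o · Σ_j s_j q_j, where q_j are
  the quartile scores of the generated concentrations and the signed
  shares s_j sum to 1.  Generating on the log2 scale makes the qgcomp
  estimand exactly recoverable and maps truth directly to the reported
  percent difference via (2^Ψ − 1)·100.  Intercepts are calibrated within
  sex so the realized arithmetic means match the configured targets
  exactly; a consequence is that cohort-level outcome means barely vary
  across cohorts, so sampling-variance checks use variables that are not
  mean-pinned (e.g. the concentrations themselves).
* **MetS is emergent**: the generator never draws MetS; prevalence arises
  from applying the clinical classifier to the generated measures.  Two
  constants were calibrated once to land the emergent prevalence near the
  27% target and then frozen: the bulk-spread factor (log-scale SDs set to
  0.85 of the value implied by the descriptive-table SDs, which are
  inflated by right-tail outliers a single lognormal should not carry) and
  the medication-assignment slope.  Medication and diagnosis flags are
  value-dependent (logistic in the standardized severity of the relevant
  measures, slope 3.0 on the latent/diagnosis severity), with the
  intercept solved so the sample prevalence matches the configured 20%
  (lipid), 21% (antihypertensive), 7% (diabetes), 12% (hypertension
  diagnosis), 6% (T2D diagnosis).  Under the default configuration the
  HbA1c-based and glucose-based glycemia criteria give MetS prevalences
  within ~1 percentage point of each other.
* **True mixture effects** default to magnitudes on the order of the
  motivating analysis (e.g. Ψ_HbA1c = 0.0166 on the log2 scale ≈ 1.2%,
  PFNA-dominant shares for the glycemia outcomes).  Ground-truth Ψ is
  settable per continuous risk factor; MetS and CMRS effects are emergent
  composites and cannot be set directly.
* **Design**: a single stratum of 16 equal-probability sites, lognormal
  weights with CV 0.3, and B = 500 Rao–Wu–Yue bootstrap replicate weights
  by default (the replicate count and the variance rule are configuration
  parameters, since survey programs differ).

What the synthetic benchmark does **not** emulate: a real multistage
sampling frame with nonresponse and calibration adjustments,
cycle-specific LODs, exposure–covariate confounding (concentrations are
independent of the sociodemographic covariates given sex), intra-site
outcome correlation, and real-population sex differences in MetS
prevalence.  Passing tests therefore demonstrate estimator correctness
and calibration under a realistic-but-idealized data-generating process,
not reproduction of any real-population estimate.

## Problem sizes used in validation

Estimator-calibration checks run at n = 2000 with 200 replications
(recovery of Ψ = 0.25; type-I error under Ψ = 0), modified Poisson
recovery at n = 5000 (true PR 1.5 per doubling), replicate-variance
validity with 200 independent cohorts of n = 1000 and B = 500, censored
MLE recovery at n = 5000 with 30% censoring, and the CMRS variance limit
at n = 10⁶.  The acceptance script reruns the descriptive block at
n = 20 000, the full battery at the survey-sized n = 1071 with B = 500,
and the calibration blocks at 100 replications.

## Known limitations

* The conditional qgcomp estimator equals the marginal one for gaussian
  outcomes but is a conditional PR for MetS; comparisons to
  marginalized-bootstrap implementations should expect small differences
  with covariates present.
* With 16 sites the replicate variance has ~15 effective degrees of
  freedom; Wald-1.96 intervals are mildly anticonservative (empirical
  type-I error ≈ 6–8% in the shipped checks).
* Single imputation understates the (small) uncertainty from the fill-in
  step; acceptable here because non-detects are concentrated in the
  lowest quartile, which quantization absorbs.
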