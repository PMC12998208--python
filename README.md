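# pfasmix

Survey-weighted analysis of per- and polyfluoroalkyl substance (PFAS)
mixtures and adult cardiometabolic health, built for national
biomonitoring surveys whose microdata are access-restricted: the package
ships a synthetic cohort generator with known ground-truth mixture
effects so the entire analytic chain is testable without any data access.

It is aimed at environmental epidemiologists and biostatisticians who
need, in one place:

* **exposure preparation** — a ≥ 70% detection-frequency retention rule,
  left-censored lognormal maximum likelihood with single "fill-in"
  imputation of non-detects truncated to (0, LOD), log2 transforms and
  the ∑PFAS composite;
* **outcome derivation** — metabolic syndrome (MetS, ≥ 3 of 5 harmonized
  clinical criteria with Asian-specific waist thresholds and HbA1c
  substituting fasting glucose) and a continuous cardiometabolic risk
  score built from age/sex-standardized residual Z-scores,

      CMRS = (zWC + zHbA1c + zTG − zHDL + zMAP) / √5,   zMAP = zDBP + ⅓(zSBP − zDBP);

* **estimation** — quantile g-computation for the joint mixture effect
  Ψ = Σⱼ βⱼ over quartile-scored exposures, with directional weights that
  sum to 1 within each direction; survey-weighted modified Poisson
  regression (prevalence ratios, robust/replicate variance) and linear
  regression for single-pollutant models; Rao–Wu–Yue bootstrap
  replicate-weight variance throughout, with Var = (1/B)·Σ(θ_b − θ̂)²;
* **a config-driven battery** — 3 strata × 8 outcomes × 7 models with the
  adjustment-set, exclusion and sensitivity rules of a sex-stratified
  survey analysis, emitting tidy CSV results and audit logs.

Binary mixture effects are reported as PR = exp(Ψ); log2-outcome effects
as percent differences (2^Ψ − 1)·100.

The modelling core is sklearn-style (`QGComp`, `SurveyWeightedGLM`,
`CensoredLogNormalImputer`, `CMRFStandardizer` with `fit`/`transform` and
fitted `_`-suffixed attributes); module-level functions wrap them for
script use, and a `pfasmix` CLI drives the pipeline end to end.

## Worked example

```python
import numpy as np, pandas as pd
import pfasmix as pm
from pfasmix.config import CohortConfig, PFAS_NAMES

cfg = CohortConfig(n_participants=1071, seed=1, n_replicates=500)
cohort = pm.generate_cohort(cfg)                      # ground-truth cohort
cohort, detection = pm.censor_below_lod(cohort, cfg.lod)
print(f"PFDA detection: {100*detection['PFDA']:.1f} %")

panel = pm.ExposurePanel(
    cohort[list(PFAS_NAMES)].copy(), dict(cfg.lod),
    cohort[[f"{a}_nd" for a in PFAS_NAMES]]
        .rename(columns={f"{a}_nd": a for a in PFAS_NAMES}),
)
panel = pm.filter_by_detection(panel).fit_and_impute(seed=1)
for a in panel.analytes:
    cohort[a] = panel.concentrations[a]

design = pm.generate_replicate_weights(cohort, cfg.n_replicates, seed=2)
derived = pm.derive_outcomes(pm.apply_exclusions(cohort, pm.ModelSpec("cmrs", "sum"))[0])
print(f"MetS prevalence: {100*derived['mets'].mean():.1f} %")

sub = derived.loc[~derived["med_diabetes"]]           # primary HbA1c subset
des = design.subset(cohort.index.isin(derived.index)) \
            .subset((~derived["med_diabetes"]).to_numpy())
cov = pd.DataFrame({"age10": (sub.age - 50) / 10,
                    "female": (sub.sex == "female").astype(float),
                    "smoking_ever": (sub.smoking == "ever").astype(float),
                    "mvpa10": sub.mvpa_min_per_day / 10})
fit = pm.QGComp(family="gaussian").fit(
    sub[list(PFAS_NAMES)], np.log2(sub["hba1c"].to_numpy()),
    covariates=cov, design=des)
row = pm.summarize_mixture(fit, "percent")
print(f"HbA1c %change per quartile increase: {row['estimate']:.2f}% "
      f"(95% CI {row['ci_lower']:.2f}, {row['ci_upper']:.2f}), n={row['n']}")
```

Output:

```
PFDA detection: 81.8 %
MetS prevalence: 27.6 %
HbA1c %change per quartile increase: 0.03% (95% CI -0.58, 0.64), n=948
```

The detection frequency and the emergent MetS prevalence land on the
generator's configured study conditions (~82%, ~27%).  The mixture row
reads: a simultaneous one-quartile increase in all five PFAS is
associated with a 0.03% change in HbA1c in this particular simulated
cohort of 948 non-diabetic-medicated adults — a single survey-sized draw
around the small configured truth (≈ 1.2%), with a bootstrap CI from 500
replicate-weight refits.  `fit.weights_positive_` /
`fit.weights_negative_` give each analyte's share of the effect in its
direction (each direction sums to 1).

The same analysis runs from the shell:

```bash
pfasmix simulate --seed 1 --out run/
pfasmix prepare  --cohort run/cohort.csv --seed 1 --out run/
pfasmix fit      --cohort run/cohort_prepared.csv --out run/
pfasmix report   --results run/results.csv --out run/
```

producing `results.csv` (273 tidy model rows: 168 primary + the
medication-inclusion sensitivity complements), JSON metadata, and
table-shaped summaries per outcome kind.

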