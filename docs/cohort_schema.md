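# Cohort table schema (version 1)

One row per participant.  Written/read as plain CSV by the `pfasmix` CLI.
All concentrations are in µg/L, clinical measures in the units noted.

## Identification & design

| column | type | notes |
|---|---|---|
| `id` | int | 0-based participant index |
| `survey_cycle` | int ∈ {2, 5, 6} | collection cycle |
| `site` | int | first-stage sampling site (cluster) |
| `weight` | float > 0 | main survey analysis weight |
| `rw_1` … `rw_B` | float ≥ 0 | Rao–Wu–Yue bootstrap replicate weights (present after `simulate`) |

## Demographics & lifestyle

| column | type | notes |
|---|---|---|
| `age` | float ∈ [20, 79] | years |
| `sex` | `male` / `female` | |
| `ethnicity` | `white` / `other` | |
| `asian_flag` | bool | Asian ethnicity (lower waist thresholds); subset of `other` |
| `education` | `high_school_or_less` / `secondary` / `post_secondary` | |
| `marital` | `married_common_law` / `widowed_sep_div` / `single` | |
| `smoking` | `never` / `ever` | |
| `country_of_birth` | `canada` / `foreign` | |
| `parity` | `0` / `1` / `2` / `3+`, empty for males | live births |
| `fish_meals_per_month` | float ≥ 0 | fish & shellfish consumption |
| `mvpa_min_per_day` | float ≥ 0 | moderate-to-vigorous physical activity |
| `pregnant` | bool | excluded from every analysis |
| `t1d` | bool | type 1 diabetes; excluded from every analysis |

## Exposures

For each analyte `A` in PFOA, PFOS, PFHxS, PFDA, PFNA:

| column | type | notes |
|---|---|---|
| `A` | float | plasma concentration µg/L; NaN while masked below LOD, filled in (0, LOD) after imputation |
| `A_nd` | bool | below-LOD (non-detect) indicator |

## Cardiometabolic measures

| column | unit | threshold used by the MetS classifier |
|---|---|---|
| `wc` | cm | ≥ 102 (M) / 88 (F); Asian ≥ 90 / 80 |
| `tg` | mmol/L | ≥ 1.7 |
| `hdl` | mmol/L | < 1.0 (M) / 1.3 (F) |
| `sbp` | mmHg | ≥ 130 |
| `dbp` | mmHg | ≥ 85 |
| `hba1c` | % | ≥ 5.7 |
| `glu` | mmol/L | ≥ 5.6 (auxiliary glycemia variant only) |

## Medication & diagnosis flags

`med_lipid`, `med_bp`, `med_diabetes`, `dx_hypertension`, `dx_t2d` — booleans
feeding the MetS criteria and the medication-exclusion sensitivity analyses.

## Derived columns (after `derive-outcomes`)

`wc_high`, `tg_high`, `hdl_low`, `bp_high`, `glyc_high`, `criteria_count`,
`mets`, `z_wc`, `z_hba1c`, `z_tg`, `z_hdl`, `z_sbp`, `z_dbp`, `cmrs`.
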