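# Metabolic syndrome clinical thresholds, version 1 (harmonized criteria,
# HbA1c substituting fasting glucose for non-fasting survey samples).
# Units: wc cm; tg, hdl, glu mmol/L; sbp, dbp mmHg; hba1c %.
version: 1
wc:
  male: 102.0
  female: 88.0
  asian_male: 90.0
  asian_female: 80.0
tg: 1.7
hdl:
  male: 1.0
  female: 1.3
sbp: 130.0
dbp: 85.0
hba1c: 5.7
# auxiliary glycemia criterion on non-fasting glucose (prevalence
# comparability check only; never a CMRS component)
glu: 5.6
n_criteria_required: 3
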