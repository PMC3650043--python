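# Baseline covariate distributions of the register training subsample
# (21,775 patients with type 2 diabetes, baseline 2003): per-sex means
# and SDs of continuous covariates and per-sex prevalences of smoking
# and albuminuria.  Pre-diagnosis event-history prevalences were not
# published and default to zero.
name: table1-training
proportion_female: 0.4224
continuous:
  age_at_diagnosis:
    male: {mean: 55.36, sd: 9.28}
    female: {mean: 57.15, sd: 9.55}
  diabetes_duration:
    male: {mean: 8.92, sd: 7.14}
    female: {mean: 9.02, sd: 7.17}
  hba1c:
    male: {mean: 7.34, sd: 1.18}
    female: {mean: 7.37, sd: 1.18}
  bmi:
    male: {mean: 28.84, sd: 4.44}
    female: {mean: 29.67, sd: 5.55}
  systolic_bp:
    male: {mean: 141.47, sd: 17.51}
    female: {mean: 143.76, sd: 18.66}
  diastolic_bp:
    male: {mean: 78.85, sd: 9.40}
    female: {mean: 77.11, sd: 9.38}
  tc_hdl_ratio:
    male: {mean: 4.23, sd: 1.29}
    female: {mean: 3.95, sd: 1.25}
  ldl:
    male: {mean: 2.86, sd: 0.88}
    female: {mean: 3.00, sd: 0.93}
smoking:
  male: 0.1507
  female: 0.1411
albuminuria:
  male: {macro: 0.0709, micro: 0.2016}
  female: {macro: 0.0403, micro: 0.1380}
history:
  ami: 0.0
  hf: 0.0
  stroke: 0.0
  naihd: 0.0
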