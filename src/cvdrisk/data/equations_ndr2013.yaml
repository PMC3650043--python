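# Published Weibull proportional-hazards equations for first and second
# cardiovascular events after type 2 diabetes diagnosis, estimated on a
# Swedish national diabetes register cohort (baseline 2003, five-year
# follow-up) with the Prentice-Williams-Peterson gap-time model.
#
# First-event equations run on years since diabetes diagnosis; second-
# event equations run on years since the first event of the same type.
# Linear continuous covariates are mean-centred; spline pieces enter
# uncentred.  Centering constants for the AMI equations are recoverable
# from the published worked example; the remaining constants were
# published only in supplementary material that is not redistributed
# here and are set to null — hazard ratios work without them, absolute
# risks raise a configuration error until the user supplies values
# (e.g. via cvdrisk.centering_from_cohort).
library: ndr-cvd-2013
version: "1.0"
source: "Swedish National Diabetes Register, first/second CVD event risk equations (2004-2008 follow-up)"
equations:
- event: ami
  order: first
  constant: -7.8187
  shape: 2.0537
  terms:
    female: -0.2318
    age_at_diagnosis: 0.0541
    hba1c: 0.0829
    systolic_bp: 0.0079
    ldl: 0.1161
    tc_hdl_ratio: 0.1712
    macroalbuminuria: 0.5719
    microalbuminuria: 0.2176
    smoker: 0.4938
    ami_history: 0.7469
    hf_since_diagnosis: 0.6151
  splines: []
  interactions: []
  time_terms: []
  centering:
    age_at_diagnosis: 56.02
    hba1c: 7.27
    systolic_bp: 140.92
    ldl: 2.77
    tc_hdl_ratio: 3.89
- event: ami
  order: second
  constant: -2.5755
  shape: 0.7916
  terms:
    female: 0.1887
    age_at_diagnosis: 0.0254
    ldl: 0.1745
    macroalbuminuria: 0.5478
    smoker: 0.2987
    ami_history: 0.7704
    hf_since_diagnosis: 0.3386
    duration_at_first_event: 0.0566
  splines: []
  interactions:
  - covariates: [female, ldl]
    coefficient: -0.2155
  time_terms: []
  centering:
    age_at_diagnosis: 56.64
    ldl: 2.54
    duration_at_first_event: 10.0
- event: hf
  order: first
  constant: -5.3260
  shape: 2.5986
  terms:
    female: -0.4697
    age_at_diagnosis: 0.0896
    tc_hdl_ratio: 0.1146
    bmi: 0.0631
    macroalbuminuria: 0.7841
    microalbuminuria: 0.6932
    smoker: 0.3402
    hf_history: 1.6988
  splines:
  - covariate: hba1c
    knot: 7.0
    coef_low: -0.2424
    coef_high: 0.1864
  - covariate: systolic_bp
    knot: 140.0
    coef_low: -0.0186
    coef_high: 0.0050
  interactions: []
  time_terms:
  - covariate: female
    form: linear
    coefficient: 0.0172
  - covariate: microalbuminuria
    form: linear
    coefficient: -0.0202
  centering:
    age_at_diagnosis: null
    tc_hdl_ratio: null
    bmi: null
- event: hf
  order: second
  constant: 0.2870
  shape: 0.8149
  terms:
    female: -0.1224
    age_at_diagnosis: 0.0207
    hba1c: 0.0579
    smoker: 0.3402
    duration_at_first_event: 0.0268
  splines: []
  interactions: []
  time_terms:
  - covariate: null
    form: step
    threshold: 1.0
    coefficient: -1.6960
  - covariate: smoker
    form: step
    threshold: 1.0
    coefficient: -0.4124
  centering:
    age_at_diagnosis: null
    hba1c: null
    duration_at_first_event: null
- event: stroke
  order: first
  constant: -7.1089
  shape: 2.0965
  terms:
    age_at_diagnosis: 0.0727
    systolic_bp: 0.0063
    diastolic_bp: 0.0113
    tc_hdl_ratio: 0.1121
    macroalbuminuria: 0.3970
    microalbuminuria: 0.2551
    smoker: 0.4010
    stroke_history: 0.9654
    hf_since_diagnosis: 0.1826
    ami_since_diagnosis: 0.3692
  splines:
  - covariate: hba1c
    knot: 7.0
    coef_low: -0.1714
    coef_high: 0.1614
  interactions: []
  time_terms: []
  centering:
    age_at_diagnosis: null
    systolic_bp: null
    diastolic_bp: null
    tc_hdl_ratio: null
- event: stroke
  order: second
  constant: -2.4119
  shape: 0.8865
  terms:
    age_at_diagnosis: 0.0288
    smoker: 0.8806
    stroke_history: 0.7675
    duration_at_first_event: 0.0518
  splines: []
  interactions: []
  time_terms:
  - covariate: smoker
    form: linear
    coefficient: -0.2326
  centering:
    age_at_diagnosis: null
    duration_at_first_event: null
- event: naihd
  order: first
  constant: -5.4122
  shape: 1.6704
  terms:
    female: -0.2278
    age_at_diagnosis: 0.0299
    hba1c: 0.0580
    tc_hdl_ratio: 0.1705
    bmi: 0.0183
    macroalbuminuria: 0.6346
    microalbuminuria: 0.1937
    smoker: 0.5724
    naihd_history: 1.4576
  splines:
  - covariate: diastolic_bp
    knot: 80.0
    coef_low: -0.0130
    coef_high: 0.0028
  interactions: []
  time_terms:
  - covariate: smoker
    form: linear
    coefficient: -0.0675
  - covariate: macroalbuminuria
    form: linear
    coefficient: -0.0300
  centering:
    age_at_diagnosis: null
    hba1c: null
    tc_hdl_ratio: null
    bmi: null
- event: naihd
  order: second
  constant: -0.5534
  shape: 0.4380
  terms:
    female: 0.0388
    tc_hdl_ratio: 0.0935
    macroalbuminuria: -0.3725
  splines: []
  interactions:
  - covariates: [female, macroalbuminuria]
    coefficient: 0.5990
  time_terms:
  - covariate: null
    form: step
    threshold: 3.0
    coefficient: -0.3295
  centering:
    tc_hdl_ratio: null
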