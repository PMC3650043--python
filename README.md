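# cvdrisk

A risk engine for **first and second cardiovascular events in type 2
diabetes**: acute myocardial infarction (AMI), heart failure (HF),
stroke, and non-acute ischaemic heart disease (NAIHD).

Health-economic simulation models of diabetes need to predict not just a
patient's *first* cardiovascular event but also subsequent ones — the
period right after a first event is by far the most hazardous, and
covariate effects differ between first and second events (e.g. female
sex is protective for a first AMI but not for a second).  This package
implements the published Swedish register-based equations for those
risks and everything needed to work with them offline:

- **`cvdrisk.equations`** — the eight published Weibull
  proportional-hazards equations (4 event types × first/second event) as
  a machine-readable config, with linear predictors, hazards, cumulative
  hazards, interval risks, hazard ratios, and hazard curves;
- **`cvdrisk.cohort`** — a synthetic baseline-cohort generator matching
  the published per-sex covariate distributions, plus annual covariate
  drift;
- **`cvdrisk.microsim`** — a patient-level microsimulator of first and
  second event histories (delayed entry, annual covariate updates,
  event-history feedback between processes, gap-time second-event
  clocks);
- **`cvdrisk.estimation`** — maximum-likelihood fitting of Weibull PH
  models on counting-process data with left truncation and time-varying
  covariates (the computation behind the published coefficient tables);
- **`cvdrisk.validation`** — Harrell's C for censored data and the
  modified Hosmer–Lemeshow calibration test with Gronnesby–Borgan
  expected event counts;
- **`cvdrisk.cli`** — `cvdrisk predict / make-cohort / simulate / fit /
  validate` for shell use.

## The model

Each equation is a Weibull proportional-hazards model

```
h(t) = exp(LP(x, t)) · p · t^(p−1)
```

where `p` is the Weibull shape and `LP` is a linear predictor over
mean-centred continuous covariates, 0/1 indicators, linear-spline
pieces, covariate interactions, and covariate-by-time interactions.
First-event equations use **years since diabetes diagnosis** as the time
scale (patients enter at their current diabetes duration — left
truncation).  Second-event equations follow the
Prentice–Williams–Peterson **gap-time** convention: the clock restarts
at zero at the first event of the same type, with a separate baseline
hazard.  All shipped first-event shapes are above one (risk rises with
diabetes duration); all second-event shapes are below one (the hazard of
a second event is highest immediately after the first).

The risk of an event in an interval `[t0, t1]`, for a patient event-free
at `t0` with covariates held fixed, is `1 − exp(−exp(LP)·(t1^p − t0^p))`.

## Worked example

```python
from cvdrisk import EquationLibrary, worked_example_profile

library = EquationLibrary.default()
profile = worked_example_profile()   # 58-year-old non-smoking male,
                                     # 10 years since diagnosis, HbA1c 8.0%,
                                     # SBP 150, TC/HDL 4.3, LDL 2.0,
                                     # macroalbuminuria

r1 = library["ami:first"].interval_risk(profile, 10, 15)
r2 = library["ami:second"].interval_risk(profile, 0, 5)
print(f"first AMI, years 10-15: {100*r1:.2f}%")
print(f"second AMI, 5 gap years: {100*r2:.2f}%")
```

prints

```
first AMI, years 10-15: 7.32%
second AMI, 5 gap years: 29.10%
```

— about 7 in 100 event-free patients have a first AMI during years 11–15
after diagnosis, while 29 in 100 patients whose first AMI occurred in
year 10 have a second AMI over the same calendar window.  That gap is
why first and second events need separate equations.

The `examples/` directory has one short script per capability
(`worked_example.py`, `hazard_ratios.py`, `simulate_cohort.py`,
`fit_recovery.py`, `validate_model.py`); each prints the numbers it
computes and a line on what they mean.

### A note on centering constants

Absolute risks require the mean-centering constants of the estimation
sample.  These are recoverable from the published worked example for the
two AMI equations (shipped in the default config); for the other six
equations they were only published in supplementary material and ship as
explicit `null`s — evaluating an absolute risk with them raises a
configuration error rather than silently assuming zero.  Hazard ratios
and shape-driven properties never need them.  For simulation studies,
`cvdrisk.centering_from_cohort(library, cohort)` fills the missing
constants from a cohort's own means.

## Command line

```bash
cvdrisk predict --equation ami:first --profile profile.csv --from 10 --to 15
cvdrisk make-cohort --n 5000 --seed 7 --out cohort.csv
cvdrisk simulate --cohort cohort.csv --equations equations.yaml --horizon 5 --seed 42 --out simdir/
cvdrisk fit --data simdir/counting_ami_first.csv --equation ami:first --out fit.json
cvdrisk validate --data simdir/counting_ami_first.csv --equation ami:first --out report.json
```

Every artifact records the seed and the SHA-256 of the equation config
used; outputs are never overwritten without `--force`.

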