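"""Discrimination and calibration of a risk equation on simulated data.

Scores every subject with their predicted 5-year first-AMI risk, then
computes Harrell's C (censoring-aware concordance) and the modified
Hosmer-Lemeshow chi-square over risk deciles with Gronnesby-Borgan
expected counts.  Because the data are simulated from the evaluated
equation itself, calibration should be good: a small HL statistic and a
non-significant p-value.
"""

import dataclasses

import numpy as np

from cvdrisk import (
    CohortSpec,
    EquationLibrary,
    generate_baseline,
    interval_cumulative_hazard,
    sample_first_event_times,
    validate_predictions,
)

library = EquationLibrary.default()
eq = library["ami:first"]

spec = dataclasses.replace(
    CohortSpec.default(), history={"ami": 0.05, "hf": 0.0, "stroke": 0.0, "naihd": 0.0}
)
rng = np.random.default_rng(23)
cohort = generate_baseline(spec, 20_000, seed=rng)
cohort["hf_since_diagnosis"] = 0

sim = sample_first_event_times(eq, cohort, horizon=5.0, rng=rng)
scores = -np.expm1(-interval_cumulative_hazard(
    eq, cohort.assign(entry=sim.entry, exit=sim.entry + 5.0)))
expected = interval_cumulative_hazard(eq, cohort.assign(entry=sim.entry, exit=sim.exit))

report = validate_predictions(
    scores, sim.exit - sim.entry, sim.event, expected,  # time on study
    df_convention="external",  # the model was not fitted on these data
    metadata={"equation": "ami:first", "score": "5-year predicted risk"},
)

c = report.concordance
print(f"Harrell's C: {c.c:.3f} (95% CI {c.ci[0]:.3f}-{c.ci[1]:.3f}, "
      f"{c.n_pairs:,} comparable pairs)")
print(f"modified HL X2: {report.hl.statistic:.2f} on {report.hl.df} df "
      f"(p = {report.hl.p_value:.3f})")
print()
print(report.hl.table.round(2).to_string(index=False))
print()
print("C near 0.7 reflects genuine risk heterogeneity in the cohort; the")
print("observed and expected decile counts agree because the scoring model")
print("is the generating model.")
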