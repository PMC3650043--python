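"""Five-year first- and second-AMI risks for the illustrative patient.

A non-smoking 58-year-old male, diagnosed with type 2 diabetes 10 years
ago, HbA1c 8.0%, systolic BP 150 mmHg, TC/HDL 4.3, LDL 2.0 mmol/L, with
macroalbuminuria and no prior cardiovascular events.
"""

from cvdrisk import EquationLibrary, worked_example_profile

library = EquationLibrary.default()
profile = worked_example_profile()

first = library["ami:first"]
second = library["ami:second"]

r1 = first.interval_risk(profile, 10, 15)
r2 = second.interval_risk(profile, 0, 5)

print(f"linear predictor, first AMI : {first.linear_predictor(profile):+.4f}")
print(f"5-year risk of a FIRST AMI (years 10-15 since diagnosis): {100*r1:.2f}%")
print(f"5-year risk of a SECOND AMI (gap years 0-5 after a first "
      f"AMI in year 10): {100*r2:.2f}%")
print()
print("About 7 in 100 event-free patients have a first AMI in years 11-15;")
print("about 29 in 100 patients who had a first AMI in year 10 have a")
print("second one over the same calendar window - the motivation for")
print("modelling first and second events separately.")
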