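"""Derived growth analytics from already-fitted parameter estimates.

Uses the packaged per-dataset reference estimates to compute the quantities
a growth study reports beyond the raw parameters: asymptotic (final) weight,
age at the inflection point, and the peak absolute growth rate (AGR).
"""

import growthcurves as gc

WINDOW = (0.0, 366.0)  # one year of ages, in days

for dataset in (1, 2):
    spec = gc.get_model("sinusoidal")
    params = gc.reference_params(dataset, "sinusoidal")
    summary = gc.summarize(spec, params, WINDOW)
    print(f"data set {dataset} (sinusoidal):")
    print(f"  asymptotic weight : {summary.asymptotic_weight:9.4f} kg")
    print(f"  inflection age    : {summary.inflection_day:9.2f} d "
          f"(~ day {round(summary.inflection_day)})")
    print(f"  AGR at inflection : {summary.agr_at_inflection:9.4f} kg/day")

# The Weibull form carries its inflection age as the parameter IP; its
# asymptote is the a parameter directly.
spec = gc.get_model("weibull")
vals = gc.reference_values(3, "weibull")
vals.setdefault("b", 0.0)  # initial-weight cell unavailable for this set
params = spec.make_params(vals)
print("data set 3 (weibull):")
print(f"  asymptotic weight : {gc.asymptotic_weight(spec, params):9.4f} kg")
print(f"  inflection age    : {vals['IP']:9.4f} d (the IP parameter)")

# A full AGR profile for plotting or tabulation:
profile = gc.agr_profile(gc.get_model("sinusoidal"),
                         gc.reference_params(1, "sinusoidal"), 0.0, 360.0, step=30.0)
print("\nmonthly AGR profile, data set 1 sinusoidal (kg/day):")
for t, v in zip(profile.times, profile.agr_values):
    print(f"  day {t:5.0f}: {v:7.4f}")
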