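"""Isotemporal substitution: what outcome difference is associated with moving
an hour of screen time into physical activity?

The engine compares model predictions at the initial and reallocated
compositions. Identity-scale outcomes get a linear-contrast CI; the
log-modelled body fat gets a MOVER interval for the difference of the
exponentiated predictions.
"""

import isotemporal as it
from isotemporal.coda import PART_NAMES

# Fit the three models on a simulated cohort (in practice: load_model files).
cfg = it.GeneratorConfig(zero_rate=0.0)
data, _ = it.generate_dataset(cfg, seed=42)
models = [
    it.fit_outcome_model(data[list(PART_NAMES)], data, data[name], name,
                         transform=cfg.outcomes[name].transform)
    for name in ("bodyfat", "psychosocial", "academic")
]

start = it.close(it.DEFAULT_CENTRE)           # the cohort compositional mean
swap = it.Reallocation({"screen": -60, "physical_activity": 60})
profile = it.CovariateProfile(sex="female", age=12.0)  # ses/puberty defaulted

report = it.substitution_report(models, start, swap, profile)
print("60 min screen time -> physical activity, from the compositional mean:")
for name, est in report.items():
    direction = "favourable" if est.favourable else "unfavourable"
    print(f"  {name:<13} {est.difference:+6.2f} "
          f"[{est.ci_low:.2f}, {est.ci_high:.2f}]  "
          f"({est.percent_difference:+.1f}%)  {direction}")

# The same reallocation from a less active starting day gives different
# estimates -- second-order terms make effects depend on the starting point.
busy = it.close({"sleep": 650, "screen": 235, "physical_activity": 57,
                 "quiet": 131, "passive_transport": 35.8, "school": 189.1,
                 "domestic_selfcare": 142.1})
report2 = it.substitution_report(models, busy, swap, profile)
print("\nsame swap from a low-activity starting composition:")
for name, est in report2.items():
    print(f"  {name:<13} {est.difference:+6.2f} "
          f"[{est.ci_low:.2f}, {est.ci_high:.2f}]  "
          f"({est.percent_difference:+.1f}%)")

# Requests that would drive a part negative are rejected with a clear error.
try:
    it.apply_reallocation(start, it.Reallocation({"quiet": -80, "sleep": 80},
                                                 cap=120))
except it.ReallocationError as e:
    print("\nrejected request:", e)
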