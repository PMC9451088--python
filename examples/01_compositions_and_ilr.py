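"""Working with 24-hour activity compositions: closure, zero replacement, and
isometric log-ratio coordinates.

A day's time use is a 7-part composition (minutes/day summing to 1440); only
relative information matters, so analysis happens in ilr coordinates.
"""

import numpy as np

import isotemporal as it

# The compositional mean of the reference cohort of 11-12 year olds (min/day).
centre = it.close(it.DEFAULT_CENTRE)
print("Daily composition (min/day):")
for part, minutes in centre.as_dict().items():
    print(f"  {part:<18}{minutes:7.1f}")
print(f"  total              {centre.values.sum():7.1f}")

# Six ilr coordinates represent the seven parts without the sum constraint.
z = it.ilr(centre)
print("\nilr coordinates (pivot basis):", np.round(z, 3))
print("back-transformed sleep (min):",
      round(it.ilr_inverse(z)["sleep"], 1), "== original", centre["sleep"])

# Zero durations are replaced with 3.25 min (65% of the 5-min recall frame)
# before taking log ratios; the other parts shrink to keep the 1440-min total.
with_zero = it.close([700, 200, 140, 0, 40, 120, 240])
replaced = it.replace_zeros_fixed(with_zero)
print("\nzero quiet time imputed at:", replaced["quiet"], "min",
      "| total still", round(replaced.values.sum(), 6), "min")

# A 3-day recall (2 weekdays, 1 weekend day) combines at 5:2 weighting.
weekday = it.close([600, 200, 160, 80, 40, 160, 200])
weekend = it.close([660, 200, 160, 80, 40, 100, 200])
weekly = it.weighted_weekly_composition(
    [weekday, weekday, weekend], ["weekday", "weekday", "weekend"])
print("\nweekly sleep at 5:2 weighting:", round(weekly["sleep"], 2),
      "min  (= (5*600 + 2*660)/7)")
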