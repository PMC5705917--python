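"""Survival kinetics of growth-arrested cultures in light versus dark.

Exponential die-off with a dark rate of ln(1e4)/10 per day reproduces a
four-order-of-magnitude viability collapse within ten days of arrest,
against full survival when light keeps ATP supply running.
"""

import math

import tnscreen as tn

dark_rate = math.log(1e4) / 10
curve = tn.simulate_viability(death_rate_light=0.0,
                              death_rate_dark=dark_rate,
                              duration=35, n_points=8)
print("day   light      dark")
for _, row in curve.iterrows():
    print(f"{row.day:4.0f}  {row.survival_light:8.2g}  {row.survival_dark:9.3g}")

# By day 10 the dark culture is down to ~1e-4 of its starting viability
# while the lit culture holds at 1.0 — the contrast that motivates
# screening for genes required specifically during energized growth arrest.
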