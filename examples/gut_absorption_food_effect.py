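"""Mechanistic gut absorption of atorvastatin: fasted vs fed.

Runs the segmented-gut model (stomach, duodenum, jejunum I/II, ileum I-IV,
colon) with the drug's fasted (FaSSIF) and fed (FeSSIF) release kinetics.
Fed-state gastric emptying is slower and fed dissolution is much slower, so
solid drug transits further down the gut before dissolving; because
enterocyte CYP3A4 density falls aborally, distally absorbed drug escapes
gut-wall metabolism more often (higher fg).
"""

import numpy as np

from oralbe.compound import load_compound
from oralbe.gut_absorption import SI_NAMES, build_physiology, simulate_gut
from oralbe.synthetic_data import dose_event_for

atorvastatin = load_compound("atorvastatin")
dose_event = dose_event_for(atorvastatin, "single")

regions = list(SI_NAMES) + ["colon"]
for state in ("fasted", "fed"):
    result = simulate_gut(atorvastatin, dose_event, build_physiology(state))
    print(f"\n{state}:")
    print(f"  fa (fraction absorbed)        = {result.fa:.3f}")
    print(f"  fg (escaping gut metabolism)  = {result.fg:.3f}")
    print(f"  gut-wall fraction metabolized = {result.fraction_metabolized:.3f}")
    print(f"  mass balance                  = {result.mass_check:.9f}")
    shares = ", ".join(
        f"{name} {fa:.1%}" for name, fa in zip(regions, result.regional_fa)
    )
    print(f"  regional fa: {shares}")
    site = np.sum(np.arange(8) * result.regional_fa) / result.fa
    print(f"  mean absorption site index    = {site:.2f} (0=duodenum ... 7=colon)")

print(
    "\nThe fed run absorbs the same dose more distally (higher site index),\n"
    "metabolizes less of it in the gut wall, and therefore delivers a larger\n"
    "fraction to the portal vein -- the mechanism behind the food effect on\n"
    "atorvastatin exposure."
)
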