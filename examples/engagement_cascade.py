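"""Adoption-cascade arithmetic for the three engagement scenarios.

The app's reach is a three-stage cascade over the 167,356 women of the
study population: aware -> downloaded (of those aware) -> push
notifications on (of those who downloaded).  Only the final group is
exposed to the app's behavioral mechanisms.
"""

import activesim as asim
from activesim.population import N_STUDY_POPULATION

scenarios = {
    "25%-25%-25%": asim.EngagementTriple(0.25, 0.25, 0.25),
    "50%-58.23%-55%": asim.EngagementTriple(0.50, 0.5823, 0.55),
    "75%-75%-75%": asim.EngagementTriple(0.75, 0.75, 0.75),
}

print(f"population: {N_STUDY_POPULATION:,} women")
for name, triple in scenarios.items():
    aware, down, notify = asim.engagement_cascade(N_STUDY_POPULATION, triple)
    print(f"{name:>15}: aware {aware:>8,} -> download {down:>8,} -> notified {notify:>8,}")
print(
    "\nThe notified column is the app's effective reach: e.g. at 25% "
    "engagement only 2,615 of 167,356 women (1.6%) ever receive a prompt."
)
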