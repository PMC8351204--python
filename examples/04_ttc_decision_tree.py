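"""Non-cancer TTC evaluation for a food-contact sulfonate salt.

A Cramer Class III compound with a cumulative daily intake of
0.35 µg/kg-bw/day is converted to a per-person exposure (x 60 kg body
weight = 21 µg/person/day) and walked through the decision tree:
cohort-of-concern check, organophosphate check, then the Class III
threshold of 90 µg/person/day. Exposure below the threshold passes —
no appreciable safety concern at this use level.
"""

from readacross import Compound, CramerClass, TTCQuery, ttc_evaluate

query = TTCQuery(
    compound=Compound.from_smiles("query", "O=S(=O)([O-])c1cccc2ccccc12.[Na+]"),
    exposure=0.35,
    exposure_unit="ug_per_kg_bw_day",
    cramer_class=CramerClass.III,
    body_weight_kg=60,
)
verdict = ttc_evaluate(query)

for question, answer in verdict.trace:
    print(f"  {question}: {answer}")
print()
print(f"outcome: {verdict.outcome.value.upper()} at node {verdict.fired_node}")
print(f"  exposure {verdict.exposure_per_person:.0f} ug/person/day "
      f"vs threshold {verdict.threshold_applied:.0f} ug/person/day")
print()
# a metal-containing compound never gets past Q1, whatever the exposure
metal = TTCQuery(
    compound=Compound.from_smiles("m", "CC[Pb](CC)(CC)CC"),
    exposure=0.001,
    exposure_unit="ug_per_person_day",
    cramer_class=CramerClass.I,
)
print(f"tetraethyllead at 0.001 ug/day: {ttc_evaluate(metal).outcome.value.upper()} "
      f"at {ttc_evaluate(metal).fired_node} (cohort of concern is exposure-independent)")
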