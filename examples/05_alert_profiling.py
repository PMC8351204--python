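"""Structural-alert screening and endpoint enrichment z-scores.

Screens the hair-dye fixture against the bundled chemotype alert
library (quinone precursors, aromatic nitro/amine DNA binders, and the
nitroaromatic reproductive-toxicant pattern), then shows how a
chemotype/endpoint association is quantified as a two-proportion
z-score with its colour-legend strength bin.
"""

from readacross import (
    bin_z,
    default_alert_library,
    enrichment_z,
    generate_fixture_library,
    screen_library,
)

bundle = generate_fixture_library("hair_dyes")
alerts = default_alert_library()
flags = screen_library(bundle.library, alerts)
print("category flags (True = at least one alert in the category matches):")
print(flags.to_string())
print()
print("The reproductive-toxicant nitroaromatic pattern fires only on the two")
print("'similar' compounds — structural grounds for not promoting them to analogues.")
print()

# enrichment: 9 of 10 chemotype members show the endpoint vs 10 of 90 outside
z = enrichment_z(hits_in_subset=9, subset_size=10, hits_total=19, total=100)
print(f"enrichment example: 9/10 hits inside vs 10/90 outside -> z = {z:.2f} ({bin_z(z)})")
print("z >= 2 marks a strongly positive chemotype/endpoint association.")
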