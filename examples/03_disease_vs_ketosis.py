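"""Compare the schizophrenia and ketogenic-intervention consensus profiles.

Loads the packaged published-table profiles and classifies each shared
pathway's genes as concordant (same consensus direction in disease and
ketosis) or discordant (opposite directions), printing the TCA cycle and
electron transport chain results.
"""
from pathvote import compare_profiles, comparison_counts, make_fixture_profiles

profiles = make_fixture_profiles()
report = compare_profiles(profiles["SCZ"], profiles["KI"])

for pathway in ("Tricarboxylic Acid (TCA) Cycle", "Electron Transport Chain (ETC)"):
    comp = report.pathways[pathway]
    print(pathway)
    print(f"  discordant: {', '.join(r.gene for r in comp.discordant)}")
    print(f"  concordant: {', '.join(r.gene for r in comp.concordant)}")
    print(f"  disease-only: {len(comp.disease_only)}, "
          f"ketosis-only: {len(comp.ketosis_only)}")

counts = comparison_counts(report)
print(f"\ntotal: {int(counts['n_concordant'].sum())} concordant, "
      f"{int(counts['n_discordant'].sum())} discordant gene-pathway pairs")

# Discordant genes (e.g. CS, SDHA, SUCLG2 in the TCA cycle: up in
# schizophrenia, down in ketosis) are candidates for a ketosis-driven
# reversal of the disease expression signature.
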