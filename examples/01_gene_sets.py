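"""Load the packaged metabolic pathway gene sets and inspect shared genes.

Prints the number of pathways, the total gene-pathway entries queried (242),
the deduplicated gene union, and which pathways share hexokinase and
succinate dehydrogenase genes.
"""
from pathvote import cross_pathway_membership, default_gene_sets

collection = default_gene_sets()
print(f"pathways: {len(collection)}")
print(f"gene-pathway entries declared: {collection.total_declared}")
print(f"distinct genes: {len(collection.gene_union())}")
for note in collection.validation_notes:
    print(f"validation note: {note}")

membership = cross_pathway_membership(collection).set_index("gene")
for gene in ("HK1", "SDHA"):
    print(f"{gene} appears in: {', '.join(membership.loc[gene, 'pathways'])}")

# The totals count gene-pathway pairs: shared genes such as HK1 (glycolysis,
# glycogenesis, pentose phosphate) make the union smaller than 242.
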