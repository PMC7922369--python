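"""Classify homeolog components: groups, clusters, pairs, orphans.

Builds a homology graph from pairwise distances and classifies each
connected component by its subgenome composition, including subgenome
inference for an unplaced gene.
"""

from homeobias import GeneModel, build_homology_graph, classify_components, infer_subgenome, summarize_components

genes = {
    # a complete triad on chromosome 3
    "g1A": GeneModel(id="g1A", chromosome="3A", start=10_000, end=11_000),
    "g1B": GeneModel(id="g1B", chromosome="3B", start=12_000, end=13_000),
    "g1D": GeneModel(id="g1D", chromosome="3D", start=9_000, end=10_000),
    # a pair: the D homeolog was lost
    "g2A": GeneModel(id="g2A", chromosome="5A", start=40_000, end=41_000),
    "g2B": GeneModel(id="g2B", chromosome="5B", start=42_000, end=43_000),
    # an unplaced gene homologous to the pair
    "g2u": GeneModel(id="g2u", chromosome="unplaced", start=1, end=1_000),
    # an orphan
    "g3D": GeneModel(id="g3D", chromosome="1D", start=5_000, end=6_000),
}
edges = [
    ("g1A", "g1B", 0.10), ("g1B", "g1D", 0.12),
    ("g2A", "g2B", 0.08), ("g2A", "g2u", 0.15),
]
components = build_homology_graph(genes, edges, link_threshold=0.35)
classify_components(components, genes)

for c in components:
    print(f"{c.id}: {c.component_class:10s} members={','.join(c.members)} "
          f"inferred={c.inferred_subgenomes}")
print(summarize_components(components).to_string(index=False))
# The unplaced gene g2u joins the 5A/5B component; its partners cover
# exactly two subgenomes, so it is speculated to be the missing D copy,
# which completes the component into a group.
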