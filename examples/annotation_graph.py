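"""Group redundant enriched annotations with a similarity graph.

Overlapping annotations clutter enrichment tables.  This example builds a
Jaccard-weighted annotation graph (edges kept at similarity >= 0.8),
extracts its connected components -- candidate "themes" of related terms
-- and shows the induced ancestor graph of significant terms inside a toy
ontology hierarchy.
"""

from annocompare import (
    AnnotationCollection,
    OntologyDag,
    assign_membership,
    build_graph,
    connected_components,
    filter_significant,
    induced_ancestor_graph,
)
from annocompare.enrichment import EnrichmentResult

# three near-duplicate annotations plus one unrelated
coll = AnnotationCollection(
    members={
        "go:axon": frozenset({"g1", "g2", "g3", "g4", "g5"}),
        "go:axon_reg": frozenset({"g1", "g2", "g3", "g4", "g6"}),
        "go:axon_dev": frozenset({"g1", "g2", "g3", "g4", "g5", "g6"}),
        "go:lipid": frozenset({"g20", "g21", "g22"}),
    },
    description={
        "go:axon": "axonogenesis",
        "go:axon_reg": "regulation of axonogenesis",
        "go:axon_dev": "axon development",
        "go:lipid": "lipid transport",
    },
)


def sig(list_id, aids):
    results = [
        EnrichmentResult(a, list_id, 3, 10, 5, 100, 0.002) for a in aids
    ]
    return filter_significant(results, p_cutoff=0.01, min_features=2)


table = assign_membership(
    [sig("SKIN", ["go:axon", "go:axon_dev", "go:lipid"]),
     sig("MUSCLE", ["go:axon_reg", "go:axon_dev"])]
)

g = build_graph(table, coll, measure="jaccard", threshold=0.8)
print(f"graph: {g.graph.number_of_nodes()} nodes, {g.graph.number_of_edges()} edges "
      f"(jaccard >= {g.threshold})")
for i, comp in enumerate(connected_components(g)):
    names = ", ".join(coll.describe(a) for a in comp)
    print(f"  component {i}: {names}")

dag = OntologyDag(
    frozenset(
        {
            ("go:axon", "go:axon_dev", "is_a"),
            ("go:axon_dev", "go:neuro", "is_a"),
            ("go:neuro", "go:bp", "is_a"),
            ("go:lipid", "go:transport", "is_a"),
            ("go:transport", "go:bp", "is_a"),
        }
    )
)
anc = induced_ancestor_graph({aid: {"membership": table.label(aid)} for aid in table.annotation_ids() if aid in dag.nodes()}, dag)
print(f"\ninduced ancestor graph: {anc.graph.number_of_nodes()} nodes, "
      f"{anc.graph.number_of_edges()} child->parent edges")
for node in sorted(anc.graph.nodes):
    d = anc.graph.nodes[node]
    role = "significant" if d.get("significant") else "ancestor"
    print(f"  {node:<15} {role}")

print(
    "\nComponents collect near-duplicate annotations into one theme; the"
    "\nancestor graph places significant terms in their ontology context."
)
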