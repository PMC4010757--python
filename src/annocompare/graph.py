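"""Annotation similarity graphs and ontology induced-ancestor graphs.

Highly similar or hierarchically related annotations are redundant in long
result tables; a graph view groups them.  Each node is an annotation
carrying its description, list-membership label, per-list p-values and
member count; edges are weighted by member-set similarity (Jaccard,
overlap, or a convex combination) and pruned below a threshold (default
0.8).  Connected components of the pruned graph are the automated aid for
spotting clusters of related terms; naming those clusters remains a human
task.

For DAG-structured ontologies, the induced ancestor graph places the
significant terms in their hierarchy: nodes are the significant terms plus
every ancestor, edges point child -> parent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

from .membership import MembershipTable
from .types import AnnotationCollection, OntologyDag

__all__ = [
    "AnnotationGraph",
    "similarity",
    "build_graph",
    "connected_components",
    "induced_ancestor_graph",
    "export_graph",
]

Measure = Literal["jaccard", "overlap", "combined"]


def similarity(
    a: Iterable[str],
    b: Iterable[str],
    measure: Measure = "jaccard",
    combined_k: float = 0.5,
) -> float:
    """Member-set similarity between two annotations.

    * ``jaccard`` = |a n b| / |a u b| (general collections)
    * ``overlap`` = |a n b| / min(|a|, |b|) (suits nested ontology sets)
    * ``combined`` = k * jaccard + (1 - k) * overlap
    """
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("similarity of an empty member set is undefined")
    inter = len(sa & sb)
    if measure == "jaccard":
        return inter / len(sa | sb)
    if measure == "overlap":
        return inter / min(len(sa), len(sb))
    if measure == "combined":
        if not 0.0 <= combined_k <= 1.0:
            raise ValueError("combined_k must lie in [0, 1]")
        jac = inter / len(sa | sb)
        ove = inter / min(len(sa), len(sb))
        return combined_k * jac + (1.0 - combined_k) * ove
    raise ValueError(f"unknown measure {measure!r}")


@dataclass
class AnnotationGraph:
    """A weighted annotation graph plus the settings that built it."""

    graph: nx.Graph  # nx.DiGraph for induced ancestor graphs
    measure: str = "jaccard"
    combined_k: float = 0.5
    threshold: float = 0.8
    directed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.directed = self.graph.is_directed()
        for u, v in self.graph.edges():
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
        if not self.directed:
            for u, v, w in self.graph.edges(data="weight", default=1.0):
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"edge ({u}, {v}) weight {w} outside [0, 1]")

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (u, v, d.get("weight", 1.0)) if (self.directed or u <= v)
            else (v, u, d.get("weight", 1.0))
            for u, v, d in self.graph.edges(data=True)
        )


def build_graph(
    table: MembershipTable,
    coll: AnnotationCollection,
    measure: Measure = "jaccard",
    combined_k: float = 0.5,
    threshold: float = 0.8,
    restrict_to: Iterable[str] | None = None,
) -> AnnotationGraph:
    """Similarity graph over the annotations of a membership table.

    Isolated nodes are retained: an annotation with no sufficiently similar
    partner is still a result.  ``restrict_to`` optionally intersects member
    sets with a feature universe before computing similarities (e.g. the
    union of the experiments' universes); by default full member sets are
    used.
    """
    missing = [a for a in table.annotation_ids() if a not in coll]
    if missing:
        raise KeyError(f"annotations absent from collection: {missing[:5]}")
    restrict = frozenset(restrict_to) if restrict_to is not None else None

    g = nx.Graph()
    member_sets: dict[str, frozenset[str]] = {}
    for aid in table.annotation_ids():
        mem = coll.members[aid]
        if restrict is not None:
            mem = mem & restrict
        member_sets[aid] = mem
        g.add_node(
            aid,
            description=coll.describe(aid),
            membership=table.label(aid),
            member_count=len(mem),
            **{f"p_{lid}": p for lid, p in table.p_values[aid].items()},
            **{
                f"significant_{lid}": (lid in table.membership[aid])
                for lid in table.lists
            },
        )
    aids = table.annotation_ids()
    for i, a in enumerate(aids):
        if not member_sets[a]:
            continue
        for b in aids[i + 1 :]:
            if not member_sets[b]:
                continue
            w = similarity(member_sets[a], member_sets[b], measure, combined_k)
            if w >= threshold:
                g.add_edge(a, b, weight=w)
    return AnnotationGraph(
        graph=g, measure=measure, combined_k=combined_k, threshold=threshold
    )


def connected_components(g: AnnotationGraph) -> list[list[str]]:
    """Maximal connected node groups, largest first, ties lexicographic.

    On the thresholded similarity graph these are the clusters of highly
    related (possibly redundant) annotations a reviewer would name as one
    theme.
    """
    base = g.graph.to_undirected() if g.directed else g.graph
    comps = [sorted(c) for c in nx.connected_components(base)]
    return sorted(comps, key=lambda c: (-len(c), c))


def induced_ancestor_graph(
    significant: Mapping[str, Mapping[str, object]] | Iterable[str],
    dag: OntologyDag,
) -> AnnotationGraph:
    """Directed graph of significant ontology terms plus all ancestors.

    ``significant`` is either an iterable of term ids or a mapping
    id -> node-attribute dict (e.g. membership metadata).  The node set is
    the transitive closure over child -> parent edges; pure-ancestor nodes
    are flagged ``significant=False`` so viewers can de-emphasise context
    terms.
    """
    if isinstance(significant, Mapping):
        seeds = dict(significant)
    else:
        seeds = {aid: {} for aid in significant}

    parent_map: dict[str, set[str]] = {}
    for child, parent, _rel in dag.edges:
        parent_map.setdefault(child, set()).add(parent)

    included: set[str] = set(seeds)
    frontier = list(seeds)
    while frontier:
        node = frontier.pop()
        for parent in parent_map.get(node, ()):
            if parent not in included:
                included.add(parent)
                frontier.append(parent)

    g = nx.DiGraph()
    for node in included:
        attrs = dict(seeds.get(node, {}))
        attrs["significant"] = node in seeds
        g.add_node(node, **attrs)
    for child, parent, rel in dag.edges:
        if child in included and parent in included:
            g.add_edge(child, parent, relation=rel)
    return AnnotationGraph(graph=g, measure="ontology", threshold=0.0)


def _write_sif(g: AnnotationGraph, prefix: Path) -> list[Path]:
    sif = prefix.with_suffix(".sif")
    node_attrs = prefix.parent / (prefix.name + ".nodes.tsv")
    edge_attrs = prefix.parent / (prefix.name + ".edges.tsv")
    relation = "child_of" if g.directed else "similar_to"

    with open(sif, "w", encoding="utf-8") as handle:
        written: set[str] = set()
        for u, v, _w in g.edges():
            handle.write(f"{u}\t{relation}\t{v}\n")
            written.update((u, v))
        for node in g.nodes():
            if node not in written:
                handle.write(f"{node}\n")

    attr_keys = sorted({k for _n, d in g.graph.nodes(data=True) for k in d})
    with open(node_attrs, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["id"] + attr_keys)
        for node in g.nodes():
            data = g.graph.nodes[node]
            writer.writerow([node] + [data.get(k, "") for k in attr_keys])
    with open(edge_attrs, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["source", "target", "weight"])
        for u, v, w in g.edges():
            writer.writerow([u, v, w])
    return [sif, node_attrs, edge_attrs]


def _write_tsv(g: AnnotationGraph, prefix: Path) -> list[Path]:
    node_path = prefix.parent / (prefix.name + ".nodes.tsv")
    edge_path = prefix.parent / (prefix.name + ".edges.tsv")
    attr_keys = sorted({k for _n, d in g.graph.nodes(data=True) for k in d})
    with open(node_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["id"] + attr_keys)
        for node in g.nodes():
            data = g.graph.nodes[node]
            writer.writerow([node] + [data.get(k, "") for k in attr_keys])
    with open(edge_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["source", "target", "weight"])
        for u, v, w in g.edges():
            writer.writerow([u, v, w])
    return [node_path, edge_path]


def export_graph(
    g: AnnotationGraph,
    prefix: str | Path,
    format: Literal["graphml", "sif", "tsv"] = "graphml",
) -> list[Path]:
    """Write the graph for external viewers; returns the paths written.

    ``graphml`` is lossless for node metadata and edge weights and
    round-trips through any GraphML reader; ``sif`` (plus node/edge
    attribute TSVs) suits Cytoscape-style import; ``tsv`` is the bare
    node/edge table pair.
    """
    prefix = Path(prefix)
    if format == "graphml":
        out = prefix if prefix.suffix == ".graphml" else prefix.with_suffix(".graphml")
        graph = g.graph.copy()
        graph.graph.update(
            measure=g.measure, combined_k=g.combined_k, threshold=g.threshold
        )
        nx.write_graphml(graph, out)
        return [out]
    if format == "sif":
        return _write_sif(g, prefix)
    if format == "tsv":
        return _write_tsv(g, prefix)
    raise ValueError(f"unknown export format {format!r}")
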