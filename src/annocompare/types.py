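"""Core domain types.

The package compares high-throughput experiments at the level of feature
*annotations* (GO terms, pathways, ...) rather than shared features.  The
types here carry the minimal state the rest of the package needs:

* :class:`FeatureList` -- one experiment's selected features together with
  the universe of everything that was measured (the reference population
  for over-representation testing).
* :class:`AnnotationCollection` -- a gene-set collection mapping annotation
  ids to member feature sets.
* :class:`OntologyDag` -- a child->parent edge table for ontologies whose
  terms form a directed acyclic graph (e.g. the Gene Ontology).
* :class:`FixtureSpec` -- parameters for the synthetic collection generator
  used throughout the test-suite and simulations.

Feature ids are opaque, case-sensitive strings; no identifier mapping is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "FeatureList",
    "AnnotationCollection",
    "OntologyDag",
    "FixtureSpec",
]


@dataclass(frozen=True)
class FeatureList:
    """One experiment's features of interest plus its measurement universe.

    Parameters
    ----------
    list_id:
        Human-readable label, e.g. ``"SKIN.Up"``.
    features:
        The selected features (e.g. differentially expressed genes).
    universe:
        Everything measured in the experiment.  Must be a superset of
        ``features``; it is the reference population for enrichment tests.
    statistic:
        Optional per-feature statistic (e.g. a moderated t-statistic).
    p_value:
        Optional per-feature p-value in [0, 1].
    """

    list_id: str
    features: frozenset[str]
    universe: frozenset[str]
    statistic: Mapping[str, float] | None = None
    p_value: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.features <= self.universe:
            extra = sorted(self.features - self.universe)[:5]
            raise ValueError(
                f"features must be a subset of the universe; "
                f"offending ids include {extra}"
            )
        for name, mapping in (("statistic", self.statistic), ("p_value", self.p_value)):
            if mapping is None:
                continue
            bad = set(mapping) - set(self.features)
            if bad:
                raise ValueError(
                    f"{name} keys must be features; unknown ids include "
                    f"{sorted(bad)[:5]}"
                )
        if self.p_value is not None:
            for fid, p in self.p_value.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"p_value[{fid!r}] = {p} outside [0, 1]")

    @classmethod
    def from_iterables(
        cls,
        list_id: str,
        features: Iterable[str],
        universe: Iterable[str],
        statistic: Mapping[str, float] | None = None,
        p_value: Mapping[str, float] | None = None,
    ) -> "FeatureList":
        return cls(list_id, frozenset(features), frozenset(universe), statistic, p_value)


@dataclass
class AnnotationCollection:
    """A gene-set collection: annotation id -> member feature set.

    Every annotation must have at least one member and ids are unique (the
    dict keys enforce uniqueness; readers raise on duplicates).
    """

    members: dict[str, frozenset[str]]
    description: dict[str, str] = field(default_factory=dict)
    namespace: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for aid, mem in self.members.items():
            if not mem:
                raise ValueError(f"annotation {aid!r} has no members")
            if not isinstance(mem, frozenset):
                self.members[aid] = frozenset(mem)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, annotation_id: str) -> bool:
        return annotation_id in self.members

    def ids(self) -> list[str]:
        return list(self.members)

    def feature_universe(self) -> frozenset[str]:
        """Union of all member sets (every annotated feature)."""
        out: set[str] = set()
        for mem in self.members.values():
            out |= mem
        return frozenset(out)

    def describe(self, annotation_id: str) -> str:
        return self.description.get(annotation_id, "")


@dataclass(frozen=True)
class OntologyDag:
    """A set of (child, parent, relation) triples forming an acyclic graph."""

    edges: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for child, parent, _rel in self.edges:
            if child == parent:
                raise ValueError(f"self-edge on {child!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm over the child->parent digraph.
        children: dict[str, set[str]] = {}
        indeg: dict[str, int] = {}
        for child, parent, _ in self.edges:
            children.setdefault(child, set())
            indeg.setdefault(child, 0)
            indeg.setdefault(parent, 0)
            if parent not in children.setdefault(child, set()):
                children[child].add(parent)
                indeg[parent] += 1
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for parent in children.get(node, ()):
                indeg[parent] -= 1
                if indeg[parent] == 0:
                    queue.append(parent)
        if seen != len(indeg):
            raise ValueError("ontology edge table contains a cycle")

    def parents_of(self, node: str) -> set[str]:
        return {p for c, p, _ in self.edges if c == node}

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for child, parent, _ in self.edges:
            out.add(child)
            out.add(parent)
        return out


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for the synthetic annotation-collection generator.

    ``overlap_rate`` biases member draws toward a shared "hub" pool of size
    ``overlap_rate * n_features``, producing tunable Jaccard structure
    between terms (0 -> independent draws from disjoint strata, 1 -> all
    terms draw from one shared pool).
    """

    n_terms: int
    size_range: tuple[int, int]
    n_features: int
    overlap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo > hi:
            raise ValueError(f"size_range min {lo} > max {hi}")
        if lo < 1:
            raise ValueError("size_range min must be >= 1")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if hi > self.n_features:
            raise ValueError(
                f"size_range max {hi} exceeds universe size {self.n_features}"
            )
        if not 0.0 <= self.overlap_rate <= 1.0:
            raise ValueError("overlap_rate must lie in [0, 1]")
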