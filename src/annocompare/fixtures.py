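"""Synthetic annotation-collection generator.

Every downstream module (enrichment, membership, graphs, simulations) is
exercised against collections built here, so no external gene-set downloads
are needed.  The generator is fully deterministic given its seed: all
randomness flows through one :class:`numpy.random.Generator` created per
call, never global state.

Overlap model: a "hub" pool of ``overlap_rate * n_features`` features is
shared by all terms; each term draws ``round(overlap_rate * size)`` members
from the hub (with re-use across terms) and the remainder from the non-hub
pool *without* re-use across terms.  ``overlap_rate = 0`` therefore yields
pairwise-disjoint terms, and raising it raises the expected pairwise
Jaccard similarity -- useful for testing similarity-graph behaviour.
"""

from __future__ import annotations

import numpy as np

from .types import AnnotationCollection, FixtureSpec

__all__ = ["generate_fixture", "stratified_collection", "feature_ids"]


def feature_ids(n: int, prefix: str = "g") -> list[str]:
    """Deterministic feature id vector ``g00000 ...``."""
    width = max(5, len(str(n - 1))) if n > 0 else 5
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _draw_terms(
    sizes: list[int],
    n_features: int,
    overlap_rate: float,
    rng: np.random.Generator,
    term_prefix: str,
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    universe = feature_ids(n_features)
    shuffled = list(np.array(universe)[rng.permutation(n_features)])
    n_hub = int(round(overlap_rate * n_features))
    hub = shuffled[:n_hub]
    free = shuffled[n_hub:]  # consumed without replacement across terms

    members: dict[str, frozenset[str]] = {}
    cursor = 0
    for t, size in enumerate(sizes):
        from_hub = min(int(round(overlap_rate * size)), len(hub), size)
        from_free = size - from_hub
        if cursor + from_free > len(free):
            raise ValueError(
                f"universe too small: term {t} needs {from_free} private "
                f"members but only {len(free) - cursor} remain "
                f"(n_features={n_features}, overlap_rate={overlap_rate})"
            )
        picked = set(free[cursor : cursor + from_free])
        cursor += from_free
        if from_hub:
            picked |= set(rng.choice(hub, size=from_hub, replace=False))
        members[f"{term_prefix}{t:04d}"] = frozenset(picked)
    return members, frozenset(universe)


def generate_fixture(spec: FixtureSpec) -> tuple[AnnotationCollection, frozenset[str]]:
    """Generate a synthetic collection plus its feature universe.

    Term sizes are uniform over ``spec.size_range``; output is byte-stable
    for a given spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_terms)]
    members, universe = _draw_terms(
        sizes, spec.n_features, spec.overlap_rate, rng, term_prefix="T"
    )
    description = {aid: f"synthetic term {aid}" for aid in members}
    return AnnotationCollection(members=members, description=description), universe


def stratified_collection(
    strata: list[tuple[int, int, int]],
    n_features: int,
    overlap_rate: float = 0.0,
    seed: int = 0,
    term_prefix: str = "T",
) -> tuple[AnnotationCollection, frozenset[str]]:
    """Collection whose term sizes follow explicit strata.

    ``strata`` is a list of ``(n_terms, min_size, max_size)``; term sizes in
    each stratum are uniform over its range.  This mirrors the size
    distribution real gene-set collections show (many small terms, a tail
    of very large ones) and is the input shape the simulation studies
    expect.
    """
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    for count, lo, hi in strata:
        if lo > hi or lo < 1:
            raise ValueError(f"bad stratum ({count}, {lo}, {hi})")
        if hi > n_features:
            raise ValueError(f"stratum max {hi} exceeds universe {n_features}")
        sizes.extend(int(rng.integers(lo, hi + 1)) for _ in range(count))
    members, universe = _draw_terms(
        sizes, n_features, overlap_rate, rng, term_prefix=term_prefix
    )
    description = {aid: f"synthetic term {aid}" for aid in members}
    return AnnotationCollection(members=members, description=description), universe
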