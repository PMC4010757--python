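"""Per-feature-list annotation statistics.

Two enrichment paradigms are supported:

* **Set-based, threshold-based (SBTB)** -- a feature set is defined by a
  threshold (e.g. differentially expressed genes), and each annotation is
  tested for over-representation in the set against the measurement
  universe with the one-sided (upper-tail) hypergeometric test:

  .. math::

     p = \\sum_{i=k}^{\\min(n, K)} \\frac{\\binom{K}{i}\\binom{N-K}{n-i}}
                                        {\\binom{N}{n}}

  with ``N`` the universe size, ``K`` the annotated features in the
  universe, ``n`` the feature-list size and ``k`` the annotated features in
  the list.

* **Rank-based, threshold-free (RBTF)** -- all measured features carry a
  statistic; an annotation is tested by comparing the mean statistic of its
  members against the means of random same-size feature subsets drawn from
  the same ranked statistic vector (a permutation gene-set test).

Filtering significant annotations uses a raw p-value cutoff (default 0.01)
plus a minimum number of annotated features; Benjamini-Hochberg adjustment
is available as an opt-in, not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .types import AnnotationCollection, FeatureList

__all__ = [
    "EnrichmentResult",
    "SignificantSet",
    "hypergeom_p",
    "hypergeom_enrich",
    "rank_enrich",
    "rank_set_test",
    "transform_p",
    "filter_significant",
    "results_to_frame",
]

UniverseMode = Literal["measured", "annotated", "intersection"]
Side = Literal["lower", "upper"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One annotation tested in one feature list."""

    annotation_id: str
    list_id: str
    n_annotated_in_list: int  # k
    n_in_list: int  # n
    n_annotated_in_universe: int  # K
    n_universe: int  # N
    p_value: float
    direction: str = "over"
    method: str = "hypergeometric"

    def __post_init__(self) -> None:
        k, n, K, N = (
            self.n_annotated_in_list,
            self.n_in_list,
            self.n_annotated_in_universe,
            self.n_universe,
        )
        if not (0 <= k <= min(n, K) and k <= n <= N and K <= N):
            raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


@dataclass
class SignificantSet:
    """The annotations retained for one list after significance filtering."""

    list_id: str
    results: list[EnrichmentResult]
    p_cutoff: float
    min_features: int
    all_results: list[EnrichmentResult] = field(default_factory=list)

    def annotation_ids(self) -> set[str]:
        return {r.annotation_id for r in self.results}


def _effective_universe(
    flist: FeatureList, coll: AnnotationCollection, universe_mode: UniverseMode
) -> frozenset[str]:
    if universe_mode == "measured":
        return flist.universe
    annotated = coll.feature_universe()
    if universe_mode == "annotated":
        return annotated
    if universe_mode == "intersection":
        return flist.universe & annotated
    raise ValueError(f"unknown universe_mode {universe_mode!r}")


def hypergeom_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``N`` universe size, ``K`` annotated features in the universe, ``n``
    feature-list size, ``k`` annotated features in the list.  Clamped to
    (0, 1] so the -log transform is always defined.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, math.ulp(0.0)), 1.0)


def hypergeom_enrich(
    flist: FeatureList,
    coll: AnnotationCollection,
    universe_mode: UniverseMode = "measured",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per annotation.

    Annotations with no member in the effective universe are omitted.  With
    ``universe_mode`` other than ``"measured"`` the feature list is first
    restricted to the effective universe (the standard convention when the
    reference population is the annotated gene space).
    """
    if not flist.features:
        raise ValueError("feature list is empty")
    universe = _effective_universe(flist, coll, universe_mode)
    if not universe:
        raise ValueError(f"effective universe empty for mode {universe_mode!r}")
    features = flist.features & universe if universe_mode != "measured" else flist.features
    N = len(universe)
    n = len(features)
    out: list[EnrichmentResult] = []
    for aid, mem in coll.members.items():
        in_universe = mem & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(features & in_universe)
        p = hypergeom_p(k, N, K, n)
        out.append(
            EnrichmentResult(
                annotation_id=aid,
                list_id=flist.list_id,
                n_annotated_in_list=k,
                n_in_list=n,
                n_annotated_in_universe=K,
                n_universe=N,
                p_value=p,
                direction="over",
                method="hypergeometric",
            )
        )
    return out


def _null_means(
    values: np.ndarray, set_size: int, n_random: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_random`` uniform without-replacement subsets of ``values``.

    Subsets are materialised batch-wise by ranking random keys, which keeps
    memory bounded while staying vectorised.
    """
    n = len(values)
    out = np.empty(n_random)
    batch = max(1, min(n_random, int(4e6 // max(n, 1))))
    done = 0
    while done < n_random:
        b = min(batch, n_random - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        out[done : done + b] = values[idx].mean(axis=1)
        done += b
    return out


def rank_set_test(
    ranked_stats: Mapping[str, float],
    member_features: Sequence[str] | set[str] | frozenset[str],
    n_random: int = 10000,
    side: Side = "lower",
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation gene-set test on a ranked statistic vector.

    The observed mean statistic over ``member_features`` is compared with
    the means of ``n_random`` random same-size subsets of the full vector.
    ``side="lower"`` asks whether the set sits at the low extreme of the
    ranking (small statistics), ``"upper"`` the opposite.  The returned
    p-value uses the add-one correction ``(b + 1) / (n_random + 1)`` so it
    is never exactly zero.
    """
    member = set(member_features)
    if not member:
        raise ValueError("member set is empty")
    unknown = member - set(ranked_stats)
    if unknown:
        raise ValueError(f"members not in ranked statistics: {sorted(unknown)[:5]}")
    if len(member) >= len(ranked_stats):
        raise ValueError("member set must be a strict subset of the ranked list")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")

    order = sorted(ranked_stats)
    values = np.array([ranked_stats[f] for f in order], dtype=float)
    observed = float(np.mean([ranked_stats[f] for f in member]))

    if rng is None:
        rng = np.random.default_rng(seed)
    nulls = _null_means(values, len(member), n_random, rng)
    if side == "lower":
        b = int(np.count_nonzero(nulls <= observed))
    elif side == "upper":
        b = int(np.count_nonzero(nulls >= observed))
    else:
        raise ValueError(f"unknown side {side!r}")
    return (b + 1) / (n_random + 1)


def rank_enrich(
    flist: FeatureList,
    coll: AnnotationCollection,
    n_random: int = 10000,
    side: Side = "lower",
    seed: int | None = 0,
) -> list[EnrichmentResult]:
    """Permutation gene-set test per annotation on a ranked feature list.

    The feature list must carry a statistic for every feature (threshold-
    free usage: the feature set is the whole measured, ranked list).
    Annotations with no member among the ranked features, or covering the
    whole list, are omitted.
    """
    if not flist.statistic:
        raise ValueError("rank_enrich requires per-feature statistics")
    stats_map = dict(flist.statistic)
    missing = flist.features - set(stats_map)
    if missing:
        raise ValueError(
            f"features lack statistics, e.g. {sorted(missing)[:5]}; "
            "rank enrichment needs a statistic for every ranked feature"
        )
    n = len(stats_map)
    rng = np.random.default_rng(seed)
    out: list[EnrichmentResult] = []
    direction = "lower-extreme" if side == "lower" else "upper-extreme"
    for aid, mem in coll.members.items():
        members = mem & set(stats_map)
        if not members or len(members) >= n:
            continue
        p = rank_set_test(stats_map, members, n_random=n_random, side=side, rng=rng)
        out.append(
            EnrichmentResult(
                annotation_id=aid,
                list_id=flist.list_id,
                n_annotated_in_list=len(members),
                n_in_list=n,
                n_annotated_in_universe=len(members),
                n_universe=n,
                p_value=p,
                direction=direction,
                method="rank_set_test",
            )
        )
    return out


def results_to_frame(results: Sequence[EnrichmentResult]):
    """Flat table view of enrichment results (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "annotation_id": r.annotation_id,
                "list_id": r.list_id,
                "k": r.n_annotated_in_list,
                "n": r.n_in_list,
                "K": r.n_annotated_in_universe,
                "N": r.n_universe,
                "p_value": r.p_value,
                "direction": r.direction,
                "method": r.method,
            }
            for r in results
        ]
    )


def transform_p(p: float) -> float:
    """Negative natural log of a p-value; the scale on which enrichment
    strength from different analyses is compared."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return -math.log(p)


def filter_significant(
    results: Sequence[EnrichmentResult],
    p_cutoff: float = 0.01,
    min_features: int = 2,
    adjust: Literal[None, "bh"] = None,
) -> SignificantSet:
    """Retain annotations with ``p <= p_cutoff`` and ``k >= min_features``.

    ``adjust="bh"`` applies Benjamini-Hochberg across the supplied results
    before thresholding (off by default; the cutoff applies to raw
    p-values).
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must lie in (0, 1]")
    if min_features < 0:
        raise ValueError("min_features must be >= 0")
    results = list(results)
    list_ids = {r.list_id for r in results}
    if len(list_ids) > 1:
        raise ValueError(f"results mix list_ids: {sorted(list_ids)}")
    list_id = results[0].list_id if results else ""

    pvals = [r.p_value for r in results]
    if adjust == "bh" and pvals:
        pvals = list(stats.false_discovery_control(pvals, method="bh"))
    retained = [
        r
        for r, p in zip(results, pvals)
        if p <= p_cutoff and r.n_annotated_in_list >= min_features
    ]
    return SignificantSet(
        list_id=list_id,
        results=retained,
        p_cutoff=p_cutoff,
        min_features=min_features,
        all_results=results,
    )
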