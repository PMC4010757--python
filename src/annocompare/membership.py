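"""List-membership over the 2^n - 1 non-empty subsets of annotation lists.

Given n feature lists, each annotation that is significant in at least one
list is assigned its *list-membership*: the exact subset of lists in which
it passed filtering.  With four lists there are 15 possible memberships,
``{A1} ... {A1,A2,A3,A4}``.  The memberships partition the significant
annotations and are the core comparative output.

This module also provides the feature-level combination baselines the
simulation studies compare against: intersecting feature lists, and
combining per-feature statistics across samples (mean t-statistic, Fisher's
method, maximum p-value).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd
from scipy import stats

from .enrichment import SignificantSet, transform_p
from .types import FeatureList

__all__ = [
    "MembershipTable",
    "enumerate_subsets",
    "assign_membership",
    "combine_features_intersection",
    "combine_statistics",
    "p_difference",
]

CombineMethod = Literal["mean_t", "fisher", "max_p"]


@dataclass
class MembershipTable:
    """Annotation -> (membership subset, per-list p-values, per-list counts)."""

    lists: list[str]
    membership: dict[str, frozenset[str]]
    p_values: dict[str, dict[str, float]]
    counts: dict[str, dict[str, int]]

    def label(self, annotation_id: str) -> str:
        """Compact dotted membership label, e.g. ``"A1.A3"``."""
        member = self.membership[annotation_id]
        return ".".join(l for l in self.lists if l in member)

    def annotation_ids(self) -> list[str]:
        return sorted(self.membership)

    def to_frame(self, descriptions: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Flat table: id, description, membership label, per-list p and flag."""
        rows = []
        for aid in self.annotation_ids():
            row: dict[str, object] = {
                "annotation_id": aid,
                "description": (descriptions or {}).get(aid, ""),
                "membership": self.label(aid),
            }
            for lid in self.lists:
                row[f"p_{lid}"] = self.p_values[aid].get(lid, float("nan"))
                row[f"significant_{lid}"] = lid in self.membership[aid]
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path, descriptions: Mapping[str, str] | None = None) -> None:
        self.to_frame(descriptions).to_csv(path, sep="\t", index=False)


def enumerate_subsets(n: int) -> list[tuple[int, ...]]:
    """All 2^n - 1 non-empty subsets of {1..n}, ordered by size then
    lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: list[tuple[int, ...]] = []
    for size in range(1, n + 1):
        out.extend(itertools.combinations(range(1, n + 1), size))
    return out


def assign_membership(sig_sets: Sequence[SignificantSet]) -> MembershipTable:
    """Assign each significant annotation its exact subset of lists.

    P-values are carried for every list in which the annotation was tested,
    significant or not, so the output table supports later inspection of
    near-misses.
    """
    if not sig_sets:
        raise ValueError("need at least one SignificantSet")
    lists = [s.list_id for s in sig_sets]
    if len(set(lists)) != len(lists):
        raise ValueError(f"duplicate list ids: {lists}")

    membership: dict[str, set[str]] = {}
    p_values: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    for sig in sig_sets:
        for res in sig.results:
            membership.setdefault(res.annotation_id, set()).add(sig.list_id)
    for sig in sig_sets:
        tested = sig.all_results if sig.all_results else sig.results
        for res in tested:
            if res.annotation_id in membership:
                p_values.setdefault(res.annotation_id, {})[sig.list_id] = res.p_value
                counts.setdefault(res.annotation_id, {})[sig.list_id] = (
                    res.n_annotated_in_list
                )
    return MembershipTable(
        lists=lists,
        membership={a: frozenset(m) for a, m in membership.items()},
        p_values=p_values,
        counts=counts,
    )


def combine_features_intersection(flists: Sequence[FeatureList]) -> FeatureList:
    """Feature-level combination: intersect feature sets and universes.

    This is the "combined sample" baseline: an annotation is then tested
    once against the intersection instead of once per list.
    """
    if not flists:
        raise ValueError("need at least one feature list")
    features = frozenset.intersection(*(f.features for f in flists))
    universe = frozenset.intersection(*(f.universe for f in flists))
    list_id = "+".join(f.list_id for f in flists)
    return FeatureList(list_id=list_id, features=features, universe=universe)


def combine_statistics(
    per_sample: Sequence[Mapping[str, float]], method: CombineMethod
) -> dict[str, float]:
    """Combine per-feature statistics across samples.

    * ``mean_t`` -- arithmetic mean per feature (for t-statistics).
    * ``fisher`` -- Fisher's method: X = -2 sum(ln p_i) ~ chi-square with
      2m degrees of freedom; returns the combined p per feature.
    * ``max_p`` -- per-feature maximum p-value (the most conservative
      combination).
    """
    if not per_sample:
        raise ValueError("need at least one sample")
    keys = set(per_sample[0])
    for i, mapping in enumerate(per_sample[1:], start=2):
        if set(mapping) != keys:
            raise ValueError(f"sample {i} has a different feature set")
    m = len(per_sample)

    if method == "mean_t":
        return {f: sum(s[f] for s in per_sample) / m for f in keys}
    if method in ("fisher", "max_p"):
        for s in per_sample:
            for f, p in s.items():
                if not 0.0 < p <= 1.0:
                    raise ValueError(f"p-value {p} for {f!r} outside (0, 1]")
        if method == "max_p":
            return {f: max(s[f] for s in per_sample) for f in keys}
        chi2 = stats.chi2(df=2 * m)
        return {
            f: float(chi2.sf(-2.0 * sum(math.log(s[f]) for s in per_sample)))
            for f in keys
        }
    raise ValueError(f"unknown combine method {method!r}")


def p_difference(sample_ps: Sequence[float], combined_p: float) -> float:
    """Transformed-p difference between the worst sample and the combined
    analysis.

    Returns ``min_i(-ln p_i) - (-ln p_combined)``: the minimum transformed
    (i.e. the *largest* raw) sample p-value minus the transformed combined
    p-value.  Positive values mean every individual sample gave stronger
    enrichment evidence than the combined list; negative values favour
    combining.
    """
    if not sample_ps:
        raise ValueError("need at least one sample p-value")
    return min(transform_p(p) for p in sample_ps) - transform_p(combined_p)
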