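"""Simulation studies: when does annotation-level comparison beat
feature-level combination?

Two hypothetical-data studies quantify the trade-off between analysing
each experiment's feature list separately (then comparing enriched
annotations) and first combining the feature lists (then running one
enrichment analysis):

* **SBTB study** (:func:`run_sbtb`) -- terms are selected from an
  annotation collection in three size strata; "differentially expressed"
  gene samples are drawn from the selected terms with an
  exponential-decay coverage model; hypergeometric enrichment p-values are
  computed per term for each sample and for the intersection of the
  samples; optionally noise genes (annotated to none of the selected
  terms) are added, with a controllable fraction shared between samples.

* **RBTF study** (:func:`run_rbtf`) -- each term is simulated in its own
  ranked list of statistics (a fixed grid of 10,000 values); a
  term-specific proportion q of the term's genes receive values from the
  extreme half of the grid in each sample; a permutation gene-set test
  yields per-sample p-values and p-values for gene-wise combined
  statistics (mean t-statistic, Fisher's method, maximum p).

Both report, per term, ``diff = min_i(-ln p_i) - (-ln p_combined)``:
positive values mean every individual sample gave stronger evidence than
the combined analysis.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import _null_means, hypergeom_p
from .membership import p_difference
from .types import AnnotationCollection

__all__ = [
    "SbtbConfig",
    "RbtfConfig",
    "select_terms",
    "sample_genes",
    "add_noise",
    "run_sbtb",
    "generate_rbtf",
    "run_rbtf",
    "summarize_by_size",
]

Strata = Sequence[tuple[int, int, int]]  # (n_terms, min_size, max_size)

SBTB_STRATA: tuple[tuple[int, int, int], ...] = ((50, 10, 100), (30, 250, 500), (20, 500, 1500))
RBTF_STRATA: tuple[tuple[int, int, int], ...] = ((50, 20, 250), (30, 250, 500), (20, 500, 1000))


def _round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1), used for all q*n counts."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _size_class_labels(strata: Strata) -> list[str]:
    if len(strata) == 3:
        return ["low", "med", "hi"]
    return [f"stratum{i}" for i in range(len(strata))]


@dataclass(frozen=True)
class SbtbConfig:
    """Conditions for the set-based threshold-based study.

    Defaults mirror the study design: 100 terms in three size strata
    (50 of 10-100 members, 30 of 250-500, 20 of 500-1500), two independent
    samples of 1000 genes each, and an exponential-decay coverage model
    with rate 3 (median fraction of a term's remaining members sampled per
    visit is about 0.23).  ``n_noise`` and ``noise_shared_fraction`` are
    grids; the full noise experiment uses 10-1000 noise genes in steps of
    10 crossed with shared fractions 0-1 in steps of 0.01
    (:meth:`noise_experiment`).
    """

    strata: Strata = SBTB_STRATA
    genes_per_sample: int = 1000
    n_samples: int = 2
    decay_rate: float = 3.0
    n_noise: Sequence[int] = (0,)
    noise_shared_fraction: Sequence[float] = (0.0,)
    n_gene_replicates: int = 1
    n_term_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_sample < 1:
            raise ValueError("genes_per_sample must be >= 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")
        for f in self.noise_shared_fraction:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"noise_shared_fraction {f} outside [0, 1]")
        for n in self.n_noise:
            if n < 0:
                raise ValueError("n_noise must be >= 0")

    @property
    def n_terms(self) -> int:
        return sum(count for count, _lo, _hi in self.strata)

    @classmethod
    def noise_experiment(cls, **overrides) -> "SbtbConfig":
        """The full noise grid: 100 noise counts x 101 shared fractions."""
        defaults = dict(
            n_noise=tuple(range(10, 1001, 10)),
            noise_shared_fraction=tuple(round(f * 0.01, 2) for f in range(0, 101)),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class RbtfConfig:
    """Conditions for the rank-based threshold-free study.

    Each term is simulated independently in a ranked list of ``n_genes``
    statistics taken from a fixed, equally spaced grid over ``stat_range``
    (default [-6, 6] for t-statistics, [0, 1] for p-values).  The
    proportion q of a term's genes placed in the extreme (significant)
    half of the grid is uniform over ``top_fraction_range`` and shared by
    both samples; which genes, and which values they get, is drawn
    independently per sample.
    """

    strata: Strata = RBTF_STRATA
    n_genes: int = 10000
    stat_kind: Literal["t_stat", "p_value"] = "t_stat"
    stat_range: tuple[float, float] | None = None
    top_fraction_range: tuple[float, float] = (0.3, 1.0)
    n_random: int = 10000
    n_samples: int = 2
    combine_methods: tuple[str, ...] | None = None
    random_grid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stat_range is None:
            rng_default = (-6.0, 6.0) if self.stat_kind == "t_stat" else (0.0, 1.0)
            object.__setattr__(self, "stat_range", rng_default)
        if self.combine_methods is None:
            methods = ("mean_t",) if self.stat_kind == "t_stat" else ("fisher", "max_p")
            object.__setattr__(self, "combine_methods", methods)
        lo, hi = self.top_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("top_fraction_range must lie within [0, 1]")
        for _count, slo, shi in self.strata:
            if shi >= self.n_genes:
                raise ValueError(
                    f"stratum max size {shi} must be < n_genes={self.n_genes}"
                )
        for m in self.combine_methods:
            if m not in ("mean_t", "fisher", "max_p"):
                raise ValueError(f"unknown combine method {m!r}")
            if m == "mean_t" and self.stat_kind != "t_stat":
                raise ValueError("mean_t combining requires stat_kind='t_stat'")
            if m in ("fisher", "max_p") and self.stat_kind != "p_value":
                raise ValueError(f"{m} combining requires stat_kind='p_value'")

    @property
    def n_terms(self) -> int:
        return sum(count for count, _lo, _hi in self.strata)


def select_terms(
    coll: AnnotationCollection,
    strata: Strata,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Stratified uniform selection of terms by member count.

    Returns ``(term_id, size_class)`` pairs in selection order.  Raises if
    a stratum has fewer qualifying (not already selected) terms than
    requested, naming the stratum.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = _size_class_labels(strata)
    chosen: list[tuple[str, str]] = []
    taken: set[str] = set()
    for label, (count, lo, hi) in zip(labels, strata):
        pool = sorted(
            aid
            for aid, mem in coll.members.items()
            if lo <= len(mem) <= hi and aid not in taken
        )
        if len(pool) < count:
            raise ValueError(
                f"stratum {label} ({count} terms of {lo}-{hi} members): only "
                f"{len(pool)} qualifying terms available"
            )
        picked = rng.choice(pool, size=count, replace=False)
        for aid in picked:
            chosen.append((str(aid), label))
            taken.add(str(aid))
    return chosen


def sample_genes(
    members: Mapping[str, frozenset[str] | set[str]],
    genes_per_sample: int,
    decay_rate: float = 3.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    max_idle_cycles: int = 100000,
) -> tuple[frozenset[str], bool]:
    """Draw one "differentially expressed" gene sample from selected terms.

    Terms are visited in ``members`` order, cycling.  On each visit a
    coverage fraction ``f = min(Exponential(rate=decay_rate), 1)`` is
    drawn and ``floor(f * remaining)`` of the term's not-yet-sampled
    members are taken uniformly without replacement; sampled genes are
    removed from every term's remaining pool.  Sampling stops when
    ``genes_per_sample`` genes are collected or the union of members is
    exhausted.

    Returns ``(genes, exhausted)`` where ``exhausted`` flags an early stop
    with fewer than ``genes_per_sample`` genes.
    """
    if genes_per_sample < 1:
        raise ValueError("genes_per_sample must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    remaining = {aid: sorted(mem) for aid, mem in members.items()}
    gene_terms: dict[str, list[str]] = {}
    for aid, mem in members.items():
        for g in mem:
            gene_terms.setdefault(g, []).append(aid)

    sample: set[str] = set()
    order = list(remaining)
    idle = 0
    while len(sample) < genes_per_sample:
        if all(len(v) == 0 for v in remaining.values()):
            return frozenset(sample), True
        progressed = False
        for aid in order:
            pool = remaining[aid]
            if not pool:
                continue
            f = min(rng.exponential(scale=1.0 / decay_rate), 1.0)
            take = min(int(f * len(pool)), genes_per_sample - len(sample))
            if take <= 0:
                continue
            picked = rng.choice(pool, size=take, replace=False)
            for g in picked:
                sample.add(str(g))
                for owner in gene_terms[str(g)]:
                    _bisect_remove(remaining[owner], str(g))
            progressed = True
            if len(sample) >= genes_per_sample:
                break
        if not progressed:
            idle += 1
            if idle > max_idle_cycles:  # pragma: no cover - probabilistic guard
                return frozenset(sample), True
        else:
            idle = 0
    return frozenset(sample), False


def _bisect_remove(sorted_list: list[str], item: str) -> None:
    i = bisect.bisect_left(sorted_list, item)
    if i < len(sorted_list) and sorted_list[i] == item:
        del sorted_list[i]


def add_noise(
    samples: Sequence[frozenset[str] | set[str]],
    noise_pool: Sequence[str],
    n_noise: int,
    shared_fraction: float,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[frozenset[str]]:
    """Add ``n_noise`` noise genes to every sample.

    ``round(shared_fraction * n_noise)`` noise genes are common to all
    samples; each sample's remainder is private and disjoint from every
    other sample's noise.  Noise genes come from ``noise_pool``, which must
    be disjoint from the selected terms' members.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_shared = _round_half_away(shared_fraction * n_noise)
    n_private = n_noise - n_shared
    need = n_shared + n_private * len(samples)
    pool = sorted(set(noise_pool))
    if len(pool) < need:
        raise ValueError(
            f"noise pool of {len(pool)} genes cannot supply {need} "
            f"(shared {n_shared} + {len(samples)} x {n_private} private)"
        )
    drawn = [str(g) for g in rng.choice(pool, size=need, replace=False)]
    shared = set(drawn[:n_shared])
    out: list[frozenset[str]] = []
    cursor = n_shared
    for s in samples:
        private = set(drawn[cursor : cursor + n_private])
        cursor += n_private
        out.append(frozenset(set(s) | shared | private))
    return out


def run_sbtb(
    coll: AnnotationCollection,
    config: SbtbConfig,
    universe: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Run the SBTB sample-wise vs combined-sample study.

    For every term-selection replicate and gene-sample replicate, and for
    every noise condition in the ``n_noise`` x ``noise_shared_fraction``
    grid, hypergeometric p-values are computed per selected term for each
    sample and for the intersection of the samples.  One row per term per
    condition, with per-sample p-values, the combined p-value, and the
    transformed-p difference.
    """
    if universe is None:
        universe = coll.feature_universe()
    N = len(universe)
    root = np.random.SeedSequence(config.seed)
    term_seeds = root.spawn(config.n_term_replicates)

    rows: list[dict] = []
    for term_rep, term_seed in enumerate(term_seeds):
        streams = term_seed.spawn(config.n_gene_replicates + 1)
        rng_terms = np.random.default_rng(streams[0])
        selected = select_terms(coll, config.strata, rng=rng_terms)
        members = {aid: coll.members[aid] & universe for aid, _ in selected}
        size_class = dict(selected)
        union_members: set[str] = set()
        for mem in members.values():
            union_members |= mem
        noise_pool = sorted(universe - union_members)

        for gene_rep in range(config.n_gene_replicates):
            rng = np.random.default_rng(streams[gene_rep + 1])
            base = [
                sample_genes(
                    members, config.genes_per_sample, config.decay_rate, rng=rng
                )[0]
                for _ in range(config.n_samples)
            ]
            for n_noise in config.n_noise:
                for shared in config.noise_shared_fraction:
                    if n_noise > 0:
                        aug = add_noise(base, noise_pool, n_noise, shared, rng=rng)
                    else:
                        aug = [frozenset(s) for s in base]
                    combined = frozenset.intersection(*aug)
                    n_comb = len(combined)
                    for aid, _label in selected:
                        mem = members[aid]
                        K = len(mem)
                        sample_ps = [
                            hypergeom_p(len(s & mem), N, K, len(s)) for s in aug
                        ]
                        k_comb = len(combined & mem)
                        comb_p = hypergeom_p(k_comb, N, K, n_comb) if n_comb else 1.0
                        row = {
                            "term_rep": term_rep,
                            "gene_rep": gene_rep,
                            "n_noise": n_noise,
                            "shared_fraction": shared,
                            "term_id": aid,
                            "size_class": size_class[aid],
                            "combined_p": comb_p,
                            "diff": p_difference(sample_ps, comb_p),
                        }
                        for i, p in enumerate(sample_ps, start=1):
                            row[f"p_sample{i}"] = p
                        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RbtfTerm:
    """One simulated term: its own ranked list plus per-sample values."""

    term_id: str
    size_class: str
    indices: np.ndarray  # the term's gene indices in its rank list
    top_fraction: float  # q, shared across samples
    sample_values: list[np.ndarray]  # per-sample statistic vector (n_genes)


def _value_grid(config: RbtfConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.stat_range
    if config.random_grid:
        return np.sort(rng.uniform(lo, hi, size=config.n_genes))
    return np.linspace(lo, hi, config.n_genes)


def generate_rbtf(config: RbtfConfig, rng: np.random.Generator | None = None) -> list[RbtfTerm]:
    """Generate the RBTF study data.

    Each term is simulated in an independent ranked list of ``n_genes``
    statistics drawn from a fixed grid.  The extreme (significant) half of
    the grid is its numerically *lower* half -- strongly negative
    t-statistics, or p-values near zero -- matching a lower-tail gene-set
    test.  Per sample, ``round(q * size)`` of the term's genes receive
    values from the extreme half and the rest from the null half; all
    other genes receive the remaining grid values at random.

    Random draws are made in rank space, so for a given seed the generated
    structure (and hence every per-sample test p-value) is identical
    between ``stat_kind='t_stat'`` and ``'p_value'``; only the value scale
    differs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grid = _value_grid(config, rng)
    n = config.n_genes
    half = n // 2
    labels = _size_class_labels(config.strata)

    terms: list[RbtfTerm] = []
    t = 0
    for label, (count, lo, hi) in zip(labels, config.strata):
        for _ in range(count):
            size = int(rng.integers(lo, hi + 1))
            q = float(rng.uniform(*config.top_fraction_range))
            indices = rng.choice(n, size=size, replace=False)
            n_top = min(_round_half_away(q * size), size, half)
            sample_values = []
            for _s in range(config.n_samples):
                values = np.empty(n)
                top_members = rng.choice(indices, size=n_top, replace=False)
                rest_members = np.setdiff1d(indices, top_members)
                # rank slots: extreme half = 0..half-1, null half = half..n-1
                top_ranks = rng.choice(half, size=n_top, replace=False)
                rest_ranks = half + rng.choice(n - half, size=len(rest_members), replace=False)
                values[top_members] = grid[top_ranks]
                values[rest_members] = grid[rest_ranks]
                used = np.concatenate([top_ranks, rest_ranks])
                free_ranks = np.setdiff1d(np.arange(n), used)
                other_genes = np.setdiff1d(np.arange(n), indices)
                values[other_genes] = grid[rng.permutation(free_ranks)]
                sample_values.append(values)
            terms.append(
                RbtfTerm(
                    term_id=f"R{t:04d}",
                    size_class=label,
                    indices=np.sort(indices),
                    top_fraction=q,
                    sample_values=sample_values,
                )
            )
            t += 1
    return terms


def _rank_p(
    values: np.ndarray,
    member_idx: np.ndarray,
    n_random: int,
    rng: np.random.Generator,
) -> float:
    """Lower-tail permutation gene-set p on an array-valued rank list."""
    observed = float(values[member_idx].mean())
    nulls = _null_means(values, len(member_idx), n_random, rng)
    b = int(np.count_nonzero(nulls <= observed))
    return (b + 1) / (n_random + 1)


def run_rbtf(
    config: RbtfConfig,
    terms: list[RbtfTerm] | None = None,
) -> pd.DataFrame:
    """Run the RBTF sample-wise vs combined-statistics study.

    Per term and per requested combine method: lower-tail permutation
    gene-set p-values for each sample's statistic vector and for the
    gene-wise combined vector, plus the transformed-p difference.  In
    p-value mode, vectors are mapped onto [-1, 1] via ``v' = 2v - 1``
    before testing so that enrichment sits at the lower end of the list.
    """
    if terms is None:
        terms = generate_rbtf(config)

    # Test-rng streams are keyed by (seed, term, test) so that runs in
    # t-statistic and p-value mode with the same seed test identical null
    # subsets: the two modes then differ only in how samples are combined.
    method_order = {"mean_t": 0, "fisher": 1, "max_p": 2}

    is_p_mode = config.stat_kind == "p_value"
    rows: list[dict] = []
    for t_idx, term in enumerate(terms):
        idx = term.indices
        sample_ps: list[float] = []
        for s_idx, values in enumerate(term.sample_values):
            v = 2.0 * values - 1.0 if is_p_mode else values
            rng = np.random.default_rng([config.seed, 17, t_idx, s_idx])
            sample_ps.append(_rank_p(v, idx, config.n_random, rng))
        for method in config.combine_methods:
            if method == "mean_t":
                combined = np.mean(term.sample_values, axis=0)
            elif method == "max_p":
                combined = np.max(term.sample_values, axis=0)
            elif method == "fisher":
                clipped = [np.clip(v, math.ulp(0.0), 1.0) for v in term.sample_values]
                x = -2.0 * np.sum([np.log(v) for v in clipped], axis=0)
                combined = stats.chi2.sf(x, df=2 * len(term.sample_values))
            else:  # pragma: no cover - validated in config
                raise ValueError(method)
            v = 2.0 * combined - 1.0 if is_p_mode else combined
            rng = np.random.default_rng([config.seed, 23, t_idx, method_order[method]])
            comb_p = _rank_p(np.asarray(v, dtype=float), idx, config.n_random, rng)
            row = {
                "term_id": term.term_id,
                "size_class": term.size_class,
                "top_fraction": term.top_fraction,
                "method": method,
                "combined_p": comb_p,
                "diff": p_difference(sample_ps, comb_p),
            }
            for i, p in enumerate(sample_ps, start=1):
                row[f"p_sample{i}"] = p
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_size(
    results: pd.DataFrame, extra_keys: Sequence[str] = ()
) -> pd.DataFrame:
    """Median transformed-p difference grouped by term size class.

    ``extra_keys`` adds grouping columns (e.g. ``["n_noise",
    "shared_fraction"]`` for the noise experiment, or ``["method"]`` for
    the RBTF study).
    """
    keys = ["size_class", *extra_keys]
    out = (
        results.groupby(keys, as_index=False)["diff"]
        .median()
        .rename(columns={"diff": "median_diff"})
    )
    return out.sort_values(keys).reset_index(drop=True)
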