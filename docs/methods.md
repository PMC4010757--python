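# Methods

## Enrichment statistics

**Hypergeometric over-representation (SBTB).** For an annotation with K
members in the effective universe of N measured features, and a feature
list of size n containing k of those members, the one-sided upper-tail
p-value is P(X ≥ k) under the hypergeometric distribution (computed with
`scipy.stats.hypergeom.sf`, clamped into (0, 1] so the −log transform is
always defined).  Only over-representation is tested; depletion is not a
question the comparative workflow asks.  The universe defaults to the
feature list's own measured universe (`universe_mode="measured"`); the
alternatives `annotated` (union of all annotation members) and
`intersection` are provided for sensitivity analysis because real studies
are ambiguous about which population they used, and the choice shifts every
p-value.  In the non-measured modes the feature list is first restricted to
the effective universe.

**Permutation rank-set test (RBTF).** For a ranked statistic vector the
observed mean over an annotation's members is compared with the means of
`n_random` uniform without-replacement subsets of the same size (default
10,000).  The p-value uses the add-one correction (b + 1)/(n_random + 1),
so it is bounded below by 1/(n_random + 1) and never 0.  Null subsets are
materialised batch-wise by ranking uniform random keys, which bounds memory
at a few tens of MB regardless of `n_random`.  The test is exact up to
Monte-Carlo error; under the null its p-values are uniform up to
discreteness, which the calibration test verifies (rejection rate at
α = 0.05 within [0.03, 0.07] over 1000 null sets).

**Filtering.** Significance filtering retains annotations with raw
p ≤ `p_cutoff` (default 0.01) and at least `min_features` annotated
features in the list.  `min_features` defaults to 2: singleton-driven hits
are almost always annotation noise.  Benjamini–Hochberg adjustment is
available (`adjust="bh"`, via `scipy.stats.false_discovery_control`) but is
deliberately not the default — the comparative workflow thresholds raw
p-values, and changing that default would silently change every membership.

**Transformed p-values.** Enrichment strength is compared on the −ln p
scale.  Natural log is the fixed convention; any base gives the same sign
and ordering of differences.

## Membership and feature-level baselines

For n lists the 2^n − 1 non-empty subsets are enumerated in (size,
lexicographic) order so output tables are stable.  An annotation's
membership is the exact set of lists in which it passed filtering;
p-values are carried for every list in which it was *tested* so near-misses
remain visible.  Feature-level baselines: list intersection (features and
universes both intersected), and gene-wise combination of statistics —
arithmetic mean (t-statistics), Fisher's method (−2 Σ ln p ~ χ² with 2m
degrees of freedom for m samples), or the per-gene maximum p-value.  The
comparison statistic `p_difference` is min<sub>i</sub>(−ln p_i) −
(−ln p_combined): the transformed value of the *worst* individual sample
minus the transformed combined value, so a positive value means even the
weakest single-sample analysis beat the combined one.

## Annotation graphs

Similarity between annotations is Jaccard |A∩B|/|A∪B| (default for general
collections), overlap |A∩B|/min(|A|,|B|) (suited to nested ontology terms,
where a child fully contained in its parent scores 1), or the convex
combination k·jaccard + (1−k)·overlap with k defaulting to 0.5.  Edges
below the threshold (default 0.8) are dropped; isolated nodes are kept
because an annotation without similar partners is still a result.
Similarities are computed on full member sets by default; `restrict_to`
lets the caller intersect members with a measurement universe first, since
either convention is defensible.  Connected components (largest first) are
the automated grouping aid; naming a component ("amine metabolism", ...) is
inherently a human judgement and is left to the user, who gets each
component's member descriptions.  Induced ancestor graphs take the
transitive closure of significant terms over child→parent edges; ancestors
that were not themselves significant are flagged so viewers can
de-emphasise them.  Export formats (GraphML; SIF plus node/edge attribute
TSVs; bare TSV) carry all node metadata — per-list p-values and
significance flags included, which is what a viewer needs to render
pie-chart-style membership nodes.

## The SBTB simulation

The generator emulates a pair of differential-expression experiments
driven by the same biology.  A synthetic annotation collection with a
realistic size profile is built by `stratified_collection`; the study
selects terms in three size strata (defaults 50 terms of 10–100 members,
30 of 250–500, 20 of 500–1500) and draws "significant gene" samples of
1000 genes: terms are visited in selection order, cycling; each visit
draws a coverage fraction f = min(Exponential(rate), 1) and takes
⌊f · remaining⌋ of the term's not-yet-sampled members; sampled genes are
removed from every term's pool.  The exponential rate defaults to 3
(median fraction ≈ 0.23 per visit), giving realistic partial coverage of
large terms; the decay law's rate is a modelling choice and is exposed as
a parameter.  Noise genes — drawn from universe features annotated to none
of the selected terms — probe robustness: `round(shared · n_noise)` noise
genes are common to all samples, the rest private and pairwise disjoint.
All rounding of fraction·count quantities is half-away-from-zero.

Per term, hypergeometric p-values are computed for each sample and for the
intersection of the samples; the mechanism being measured is simple:
shared noise survives intersection and dilutes the combined list (raising
its p-value), while private noise is eliminated by intersecting.  The
summary operation reports median diff grouped by size class (and any
condition columns).  The full noise grid of the study design —
10–1000 noise genes in steps of 10 × shared fraction 0–1 in steps of 0.01
(100 × 101 conditions) — is available via `SbtbConfig.noise_experiment()`
but is hours of compute; tests and the acceptance script run a scaled
version (20 terms, 500-gene samples, 5 replicates, the two extreme shared
fractions at 1000 noise genes), which reproduces the direction of the
effect in seconds.

## The RBTF simulation

DAG-structured annotations make rank simulation awkward, so terms are
simulated independently: **each term gets its own ranked list** of
`n_genes` statistics (default 10,000) taken from a fixed equally spaced
grid over the statistic range ([−6, 6] for t-statistics, [0, 1] for
p-values; a uniform-random grid is available behind `random_grid`).  A
shared-list design with disjoint term index sets cannot host 100 terms of
the stated sizes inside one 10,000-gene list (the expected member slots
alone exceed 30,000), so per-term independent lists are the only reading
consistent with the stated sizes; "independent terms" then holds by
construction.  Per term, a proportion q ~ U(0.3, 1) — shared by both
samples — of its genes receive values from the *extreme* half of the grid
(the numerically lower half: strongly negative t, p near 0, i.e. the top
of the significance ranking), the rest from the null half; which genes and
which values is drawn independently per sample.  All draws are made in
rank space, so a given seed produces the identical structure in t-statistic
and p-value mode; the two modes differ only by an affine value map, under
which the mean-based permutation test is invariant.  This makes "compare
combining methods on the same generated data" exact: mean-t combining runs
in t mode, Fisher/max-p combining in p mode, same seed.  Test RNG streams
are keyed per (seed, term, test) so per-sample p-values also agree across
modes up to tie-breaking at floating-point equality (differences of at
most 1/(n_random+1)).

Per-sample and combined vectors are scored with the lower-tail permutation
test; in p-value mode vectors are first mapped onto [−1, 1] by v′ = 2v − 1
(the unique affine map of [0, 1] onto [−1, 1]) so enrichment sits at the
lower end.  Mean-t combining halves the null variance of the combined
vector and so typically strengthens evidence (negative diff); max-p
combining pushes per-gene evidence toward the null end (a gene must be
extreme in *every* sample to stay extreme) and is the most conservative.
At the scaled-down problem size used in tests and the acceptance script
(20 terms, 1000 genes, 1000 permutations) the mean-t vs max-p contrast is
reproducible at the fixed seed but individual reruns at other seeds can
invert it — with 20 terms, many of which saturate at the permutation
p-value floor, the contrast estimate carries substantial Monte-Carlo
error.  The plateau property (every method and sample detects terms with
q ≥ 0.95) is checked by generating terms with q in [0.95, 1].

## What the synthetic data does not model

Generated collections have exchangeable, unstructured feature ids: no
ontology hierarchy inside the enrichment collections (hierarchies appear
only in the explicit DAG carrier), no correlation between expression of
genes in the same term, no platform effects, and noise genes are
annotation-free by construction rather than annotated to unselected terms.
Passing simulations therefore demonstrate the combinatorial and
statistical mechanisms — dilution of intersections by shared noise,
conservatism of max-p combining — not performance on any real transcriptome.

## Numerical choices and degenerate inputs

P-values are clamped into (0, 1]; `transform_p` rejects p ≤ 0.  Empty
feature lists, empty universes, empty member sets, sets equal to the whole
ranked list, cyclic ontology edge tables, underpopulated selection strata
and undersized noise pools all raise with messages naming the offender.
Gene sampling that exhausts the union of term members returns the union
with an exhaustion flag rather than failing.  All randomness flows through
explicitly seeded `numpy.random.Generator` objects — one per call or
derived via `SeedSequence.spawn` — and both simulators are byte-stable
end to end for a fixed config.
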