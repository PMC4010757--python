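"""The SBTB and RBTF simulation studies."""

import numpy as np
import pandas as pd
import pytest

from annocompare import (
    AnnotationCollection,
    RbtfConfig,
    SbtbConfig,
    add_noise,
    generate_rbtf,
    run_rbtf,
    run_sbtb,
    sample_genes,
    select_terms,
    stratified_collection,
    summarize_by_size,
)
from annocompare.sim import RbtfTerm, _round_half_away

SMALL_STRATA = [(4, 5, 20), (3, 21, 60), (2, 61, 150)]


@pytest.fixture(scope="module")
def small_collection():
    return stratified_collection(
        [(6, 5, 20), (5, 21, 60), (4, 61, 150)],
        n_features=2000,
        overlap_rate=0.2,
        seed=31,
    )


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.5, 1), (1.5, 2), (2.4, 2), (0.49, 0), (5.0, 5)]
    )
    def test_round_half_away_from_zero(self, x, expected):
        assert _round_half_away(x) == expected


class TestSelectTerms:
    def test_exactly_matching_collection_selects_all(self):
        coll, _ = stratified_collection([(4, 5, 20)], n_features=500, seed=1)
        chosen = select_terms(coll, [(4, 5, 20)], seed=0)
        assert {aid for aid, _ in chosen} == set(coll.ids())
        assert all(label == "stratum0" for _, label in chosen)

    def test_underpopulated_stratum_named_in_error(self, small_collection):
        coll, _ = small_collection
        with pytest.raises(ValueError, match="low"):
            select_terms(coll, [(50, 5, 20), (3, 21, 60), (2, 61, 150)], seed=0)

    def test_deterministic_given_seed(self, small_collection):
        coll, _ = small_collection
        assert select_terms(coll, SMALL_STRATA, seed=5) == select_terms(
            coll, SMALL_STRATA, seed=5
        )

    def test_size_class_labels(self, small_collection):
        coll, _ = small_collection
        labels = {label for _, label in select_terms(coll, SMALL_STRATA, seed=2)}
        assert labels == {"low", "med", "hi"}


class TestSampleGenes:
    def test_single_term_source_fills_budget_exactly(self):
        members = {"T": frozenset(f"g{i}" for i in range(1500))}
        sample, exhausted = sample_genes(members, 1000, seed=3)
        assert len(sample) == 1000 and not exhausted
        assert sample <= members["T"]

    def test_exhaustion_returns_union_with_flag(self):
        members = {"T1": frozenset({"a", "b"}), "T2": frozenset({"b", "c"})}
        sample, exhausted = sample_genes(members, 100, seed=0)
        assert exhausted and sample == {"a", "b", "c"}

    def test_deterministic_given_seed(self, small_collection):
        coll, _ = small_collection
        members = dict(coll.members)
        s1, _ = sample_genes(members, 200, seed=8)
        s2, _ = sample_genes(members, 200, seed=8)
        assert s1 == s2

    def test_every_gene_annotated_to_a_selected_term(self, small_collection):
        coll, _ = small_collection
        members = dict(coll.members)
        union = set().union(*members.values())
        sample, _ = sample_genes(members, 300, seed=4)
        assert sample <= union
        assert len(sample) == 300  # no duplicates by construction (set)

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            sample_genes({"T": frozenset({"a"})}, 0)


class TestAddNoise:
    pool = [f"n{i}" for i in range(100)]

    def test_fully_shared(self):
        s1, s2 = add_noise([set(), set()], self.pool, 10, 1.0, seed=1)
        assert s1 == s2 and len(s1) == 10

    def test_fully_private(self):
        s1, s2 = add_noise([set(), set()], self.pool, 10, 0.0, seed=1)
        assert len(s1) == 10 and len(s2) == 10 and not (s1 & s2)

    def test_half_shared_rounding(self):
        s1, s2 = add_noise([set(), set()], self.pool, 10, 0.5, seed=1)
        assert len(s1 & s2) == 5
        assert len(s1) == 10 and len(s2) == 10

    def test_counts_conserved_on_nonempty_samples(self):
        base = [{"x1"}, {"x2"}]
        out = add_noise(base, self.pool, 7, 0.3, seed=2)
        assert all(len(o) == len(b) + 7 for o, b in zip(out, base))

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            add_noise([set(), set()], ["n1", "n2"], 5, 0.0, seed=0)


class TestRunSbtb:
    def test_identical_samples_give_zero_diff(self):
        # one term of exactly 40 members and a 40-gene budget: both samples
        # are the whole term, so the intersection equals each sample
        coll = AnnotationCollection(
            members={"T0": frozenset(f"g{i}" for i in range(40))}
        )
        universe = frozenset(f"g{i}" for i in range(400))
        cfg = SbtbConfig(strata=[(1, 40, 40)], genes_per_sample=40, seed=5)
        df = run_sbtb(coll, cfg, universe=universe)
        assert (df["diff"].abs() < 1e-12).all()
        assert (df["p_sample1"] == df["combined_p"]).all()

    def test_reduced_run_rows_and_diff_invariant(self, small_collection):
        coll, universe = small_collection
        cfg = SbtbConfig(
            strata=SMALL_STRATA,
            genes_per_sample=150,
            n_gene_replicates=2,
            n_noise=(20,),
            noise_shared_fraction=(0.5,),
            seed=9,
        )
        df = run_sbtb(coll, cfg, universe=universe)
        assert len(df) == 9 * 2  # terms x gene replicates
        from annocompare import p_difference

        for row in df.itertuples():
            assert row.diff == pytest.approx(
                p_difference([row.p_sample1, row.p_sample2], row.combined_p)
            )

    def test_intersection_never_beats_samples_on_counts(self, small_collection):
        # the combined sample is the intersection, so per-term k_combined
        # can never exceed either sample's k; verify via set containment
        coll, universe = small_collection
        members = dict(coll.members)
        rng = np.random.default_rng(12)
        s1, _ = sample_genes(members, 200, rng=rng)
        s2, _ = sample_genes(members, 200, rng=rng)
        combined = s1 & s2
        for mem in members.values():
            assert len(combined & mem) <= min(len(s1 & mem), len(s2 & mem))

    def test_noise_experiment_grid_dimensions(self):
        cfg = SbtbConfig.noise_experiment()
        assert len(cfg.n_noise) == 100
        assert len(cfg.noise_shared_fraction) == 101
        assert cfg.n_noise[0] == 10 and cfg.n_noise[-1] == 1000
        assert cfg.noise_shared_fraction[0] == 0.0
        assert cfg.noise_shared_fraction[-1] == 1.0

    def test_end_to_end_determinism(self, small_collection):
        coll, universe = small_collection
        cfg = SbtbConfig(strata=SMALL_STRATA, genes_per_sample=100, seed=21)
        a = run_sbtb(coll, cfg, universe=universe)
        b = run_sbtb(coll, cfg, universe=universe)
        pd.testing.assert_frame_equal(a, b)


RBTF_SMALL = dict(strata=[(4, 10, 40), (2, 41, 100)], n_genes=500, n_random=300)


class TestGenerateRbtf:
    def test_full_top_fraction_puts_all_members_in_extreme_half(self):
        cfg = RbtfConfig(**RBTF_SMALL, top_fraction_range=(1.0, 1.0), seed=2)
        terms = generate_rbtf(cfg)
        midpoint = 0.0  # t grid is symmetric about 0
        for term in terms:
            for values in term.sample_values:
                assert (values[term.indices] < midpoint).all()

    def test_p_value_mode_values_within_unit_interval(self):
        cfg = RbtfConfig(**RBTF_SMALL, stat_kind="p_value", seed=2)
        for term in generate_rbtf(cfg):
            for values in term.sample_values:
                assert values.min() >= 0.0 and values.max() <= 1.0

    def test_samples_share_q_with_independent_assignments(self):
        cfg = RbtfConfig(**RBTF_SMALL, seed=6)
        terms = generate_rbtf(cfg)
        # same expected set mean: across terms, the paired mean difference
        # between samples should be centred on zero
        diffs = [
            t.sample_values[0][t.indices].mean() - t.sample_values[1][t.indices].mean()
            for t in terms
        ]
        spread = np.std([t.sample_values[0][t.indices].mean() for t in terms])
        assert abs(np.mean(diffs)) < spread
        assert any(
            not np.array_equal(t.sample_values[0], t.sample_values[1]) for t in terms
        )

    def test_each_sample_vector_is_a_permutation_of_the_grid(self):
        cfg = RbtfConfig(**RBTF_SMALL, seed=3)
        grid = np.linspace(-6, 6, cfg.n_genes)
        for term in generate_rbtf(cfg)[:2]:
            for values in term.sample_values:
                assert np.allclose(np.sort(values), grid)


class TestRunRbtf:
    def test_identical_samples_give_near_zero_diff(self):
        rng = np.random.default_rng(4)
        values = rng.permutation(np.linspace(-6, 6, 400))
        term = RbtfTerm(
            term_id="R0",
            size_class="low",
            indices=np.arange(30),
            top_fraction=0.5,
            sample_values=[values, values.copy()],
        )
        cfg = RbtfConfig(
            strata=[(1, 30, 30)], n_genes=400, n_random=4000, seed=1
        )
        df = run_rbtf(cfg, terms=[term])
        # combined (mean of identical vectors) equals each sample vector, so
        # the only residual is Monte-Carlo noise in the permutation p-values
        row = df.iloc[0]
        assert row.p_sample1 == pytest.approx(row.combined_p, abs=0.05)
        assert abs(row["diff"]) < 0.3

    def test_smoke_run_is_finite_and_complete(self):
        cfg = RbtfConfig(**RBTF_SMALL, seed=11)
        df = run_rbtf(cfg)
        assert len(df) == 6  # one mean_t row per term
        assert np.isfinite(df["diff"]).all()
        assert ((df["p_sample1"] > 0) & (df["p_sample1"] <= 1)).all()

    def test_max_p_combining_is_worse_than_samples_for_most_terms(self):
        cfg = RbtfConfig(
            **RBTF_SMALL, stat_kind="p_value", combine_methods=("max_p",), seed=13
        )
        df = run_rbtf(cfg)
        worse = (df["combined_p"] >= df[["p_sample1", "p_sample2"]].min(axis=1)).mean()
        assert worse > 0.5

    def test_combine_method_mode_mismatch_rejected(self):
        with pytest.raises(ValueError, match="max_p"):
            RbtfConfig(**RBTF_SMALL, combine_methods=("max_p",), stat_kind="t_stat")
        with pytest.raises(ValueError, match="mean_t"):
            RbtfConfig(**RBTF_SMALL, combine_methods=("mean_t",), stat_kind="p_value")

    def test_end_to_end_determinism(self):
        cfg = RbtfConfig(**RBTF_SMALL, seed=19)
        pd.testing.assert_frame_equal(run_rbtf(cfg), run_rbtf(cfg))


class TestSummary:
    def test_median_by_size_class(self):
        df = pd.DataFrame(
            {
                "size_class": ["low", "low", "hi"],
                "diff": [1.0, 3.0, -1.0],
            }
        )
        out = summarize_by_size(df)
        assert dict(zip(out.size_class, out.median_diff)) == {"hi": -1.0, "low": 2.0}
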