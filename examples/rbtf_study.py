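"""Rank-based simulation: how the gene-wise combining method matters.

Each of 20 synthetic terms lives in its own ranked list of 1000
statistics; a term-specific proportion q of its genes sit in the
significant half of the ranking in each sample.  A permutation gene-set
test scores each sample and the gene-wise combined statistics.  Averaging
t-statistics concentrates evidence; taking the per-gene maximum p-value
is the most conservative combination and can make the combined analysis
worse than either sample.
"""

from annocompare import RbtfConfig, run_rbtf

base = dict(
    strata=[(10, 20, 100), (6, 100, 250), (4, 250, 500)],
    n_genes=1000,
    n_random=1000,
    seed=42,
)
mean_t = run_rbtf(RbtfConfig(**base))
max_p = run_rbtf(RbtfConfig(**base, stat_kind="p_value", combine_methods=("max_p",)))

print(f"mean diff, mean-t combining : {mean_t['diff'].mean():+.4f}")
print(f"mean diff, max-p combining  : {max_p['diff'].mean():+.4f}")

plateau = run_rbtf(RbtfConfig(**{**base, "top_fraction_range": (0.95, 1.0)}))
worst = plateau[["p_sample1", "p_sample2", "combined_p"]].max().max()
print(f"worst p-value when q >= 0.95: {worst:.4g}")
print(
    "\ndiff = min_i(-ln p_i) - (-ln p_combined).  Higher diff under max-p"
    "\ncombining means the conservative combination loses evidence that"
    "\nsample-wise analysis keeps; when nearly all of a term's genes are"
    "\nhighly ranked (q >= 0.95), every method detects it (plateau)."
)
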