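"""Test whether lncRNAs are co-expressed with their neighboring genes.

Each lncRNA is paired with its nearest protein-coding gene; the Pearson
correlation of the pair's expression profiles is compared, by Welch
t-test, against correlations of randomly drawn lncRNA/non-neighbor
gene pairs.  |r| > 0.8 flags a strongly correlated pair.
"""

from lncloc import FixtureSpec, coexpression_test, generate, nearest_gene
from lncloc.coexpression import bin_counts

fx = generate(FixtureSpec(seed=11))

assignments = [nearest_gene(t, fx.annotation) for t in fx.lnc_transcripts]
print("distance of each lncRNA to its nearest gene:")
for b, n in bin_counts(assignments).items():
    print(f"  {b:<8} {n}")

pairs = list(map(tuple, fx.truth_rho[["lnc_id", "gene_id"]].values))
res = coexpression_test(
    pairs,
    fx.fpkm,
    gene_ids=[t.gene_id for t in fx.reference_transcripts],
    n_random=500,
    seed=1,
)
print(f"\nneighbor pairs: {len(res.observed_r)}, random pairs: {len(res.null_r)}")
print(f"mean r (neighbors) = {res.observed_mean:.3f}")
print(f"mean r (random)    = {res.null_mean:.3f}")
print(f"Welch t = {res.t_statistic:.1f}, p = {res.p_value:.2e}")
print(f"strong pairs (|r| > 0.8): {len(res.strong_pairs)}")
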