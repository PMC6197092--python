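"""Genetic distances and differentiation between simulated populations.

Builds four subpopulations around the packaged reference table with a
known fixation index (Balding-Nichols, F_ST = 0.05), samples genotypes
from each, and computes Nei's D_A, Weir-Cockerham theta and a per-locus
permutation test of allele-frequency homogeneity.
"""

import numpy as np

import strpopkit as sk

fx = sk.reference_panel()
pops = sk.balding_nichols_freqs(fx.frequencies, k=4, f_st=0.05, seed=10)

sampled = {}
datasets = {}
for name, table in pops.items():
    ds = sk.sample_genotypes(table, 200, seed=hash(name) % 2**31)
    datasets[name] = ds
    sampled[name] = sk.frequency_table_from_genotypes(ds, name)

da, fst = sk.distance_matrices(sampled)
print("Nei D_A:")
print(da.to_dataframe().round(4).to_string())
print("\nWeir-Cockerham theta (raw, may dip below 0 for identical pairs):")
print(fst.to_dataframe().round(4).to_string())
print(f"\nmean pairwise theta = {fst.values[np.triu_indices(4, 1)].mean():.4f} "
      f"(simulated truth: 0.05)")

r = sk.differentiation_test(
    datasets["pop1"].allele_counts("TPOX"),
    datasets["pop2"].allele_counts("TPOX"),
    n_permutations=10_000, seed=11, locus="TPOX", pop_a="pop1", pop_b="pop2")
print(f"\nTPOX differentiation pop1 vs pop2: G = {r.statistic:.1f}, "
      f"P = {r.p_value:.4f}")
print("\nTheta near its simulated value shows the estimator recovers the")
print("fixation index; the permutation P tests per-locus homogeneity.")
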