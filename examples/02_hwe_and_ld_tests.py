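"""Exact tests of Hardy-Weinberg equilibrium and linkage disequilibrium.

Simulates genotypes under random mating from the packaged TPOX
frequencies, then runs the HWE exact test (Monte-Carlo, since a
7-allele locus at n = 500 has astronomically many genotype tables) and
a genotypic LD permutation test on an artificially coupled locus pair.
"""

import strpopkit as sk
from strpopkit.equilibrium import genotype_counts_at, hwe_test

fx = sk.reference_panel()
tpox = sk.FrequencyTable("tpox", {"TPOX": fx.frequencies.freqs["TPOX"]})

# HWE: data simulated under the null should give an unremarkable P
ds = sk.sample_genotypes(tpox, 500, seed=1)
r = hwe_test(genotype_counts_at(ds, "TPOX"), draws=20_000, seed=2)
print(f"HWE under random mating:   P = {r.p_value:.4f}  ({r.method}, "
      f"MC s.e. {r.mc_error:.4f})")

# strong inbreeding produces a heterozygote deficit the test detects
ds = sk.sample_genotypes(tpox, 500, f_is=0.2, seed=3)
r = hwe_test(genotype_counts_at(ds, "TPOX"), draws=20_000, seed=4)
print(f"HWE with inbreeding 0.2:   P = {r.p_value:.4f}")

# LD: locus B copies locus A half the time -> strongly dependent
ds = sk.linked_pair(tpox, 500, coupling=0.5, seed=5)
r = sk.ld_exact(ds, "A", "B", n_permutations=10_000, seed=6)
print(f"LD, coupled loci:          P = {r.p_value:.4f}  (G = {r.statistic:.1f})")

ds = sk.linked_pair(tpox, 500, coupling=0.0, seed=7)
r = sk.ld_exact(ds, "A", "B", n_permutations=10_000, seed=8)
print(f"LD, independent loci:      P = {r.p_value:.4f}")

print()
print("Small P-values flag departures: a heterozygote deficit under")
print("inbreeding for HWE, genotype association between loci for LD.")
print(f"Bonferroni level for a 20-locus panel: "
      f"{sk.bonferroni(0.05, 190):.6f} (190 pairwise tests)")
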