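# Methods

This note records the statistical conventions, simulation conditions and
numerical choices behind `strpopkit`, in the spirit of the model
documentation of packages like msprime or statsmodels.

## Data model

STR alleles are repeat counts with at most one partial-repeat digit
(8, 9.3, 29.2), stored as integer tenths so ordering and equality are
exact and string forms round-trip. Genotypes are unordered diploid
pairs; a missing call carries no alleles and is excluded locus-wise
(per-locus deletion), so each locus has its own typed count n_l — the
convention of forensic population reports, which maximizes the usable
sample at every locus. Frequency tables map locus → (allele →
frequency) with a diploid sample size per locus; published tables are
rounded to 4 decimals, so column sums are accepted within 1 ± 0.005
with a warning and are never silently renormalized (an explicit
`renormalize` flag divides by the column sum). Reproducing printed
parameters requires using printed frequencies exactly as printed.

## Forensic parameters

Conventions were fixed by verifying each candidate formula against the
packaged reference panel (max |computed − printed| < 2 × 10⁻⁴ over all
20 loci × {He, PIC, PE_duo, PE_trio}):

- **He = 1 − Σp²**, *without* the 2n/(2n−1) small-sample correction:
  the uncorrected form reproduces the printed values (e.g. TPOX
  0.61485 → “0.6148”; the corrected form gives 0.6150).
- **PIC** in the Botstein form 1 − Σp² − (Σp²)² + Σp⁴.
- **MP** is the sum of squared *observed genotype proportions*, not the
  Hardy–Weinberg expectation Σp⁴ + 2[(Σp²)² − Σp⁴]; the two differ
  (TPOX: 0.2074 observed vs 0.2087 expected), so MP/DP are reported as
  unavailable for frequency-only input.
- **PE_trio** is the Brenner form h²(1 − 2hH²) on observed
  heterozygosity; **PE_duo** the single-parent frequency form
  1 − 4Σp² + 2(Σp²)² + 4Σp³ − 3Σp⁴.
- **Combined values** multiply across loci. CDP differs from 1 by
  ~10⁻²⁵, far below float resolution, so products are evaluated in
  50-digit decimal arithmetic and reported both as floats and as digit
  strings (default 40 digits). Printed tables mix rounding and
  truncation in the 4th decimal, so comparisons use an absolute
  tolerance of 2 × 10⁻⁴ rather than string equality.

## Hardy–Weinberg exact test

The test conditions on the observed allele counts m_a. Every genotype
table with those margins has Levene probability
P = n!·2^h·Π m_a! / (Π n_g!·(2n)!); the P-value sums P over tables no
more probable than the observed one, counting ties within a relative
10⁻¹² (log-space tolerance 10⁻⁹). Complete enumeration is attempted
when n ≤ 60 and the locus has ≤ 8 alleles, with a lazy abort once
10⁵ tables have been generated; beyond that the test samples tables by
randomly pairing the 2n-allele vector — each shuffle is an unbiased
draw from the Levene distribution — and reports the +1-corrected
estimate with its binomial standard error. This independent-sampling
scheme is simpler than a Markov chain and has no mixing-time concerns;
10⁵ draws (the default) give a standard error below 0.0016 at any p.
A forensic panel at n = 2 000 with 7–24 alleles per locus is far beyond
any enumeration cap, so panel-scale tests always use Monte-Carlo.

## Linkage disequilibrium

Phase is unknown for autosomal STR genotypes, so the LD test is
genotypic: the statistic is the log-likelihood-ratio G of the genotype ×
genotype contingency table over individuals typed at both loci, and the
null is generated by permuting one locus' genotype column, which is
exact in distribution under independence. P-values carry the +1
correction, p = (1 + #{G* ≥ G_obs}) / (1 + N), hence always lie in
(0, 1]. A monomorphic locus makes the test degenerate (p = 1, flagged,
not an error). Pairwise scans over L loci apply the Bonferroni level
α / [L(L−1)/2] — 0.000263 for 20 loci at α = 0.05 — and report the
lower-triangle p-value matrix.

## Population comparison

Per-locus differentiation between two populations is a permutation
G-test on the 2 × k allele-count table, shuffling allele labels across
populations with totals held fixed (default 10⁴ permutations; the
count is a config knob since reference tools leave it unspecified).

Nei's allele-sharing distance D_A = 1 − (1/L) Σ_loci Σ_alleles √(x y)
is averaged arithmetically over the shared locus panel; absent alleles
contribute 0, so identical tables give 0 and fully disjoint ones give 1.

The fixation index uses the Weir–Cockerham variance-components ratio in
its frequency-and-sample-size form, treating the 2n_i allele copies per
population as sampling units (no genotypic heterozygosity term). This
is the form available when comparing against *published* frequency
tables, where reference genotypes are not obtainable; it is documented
as an approximation to the AMOVA-based value and validated instead by
recovering the simulated fixation index of Balding–Nichols populations
(regression slope of θ̂ on true F within [0.8, 1.2] across
F ∈ {0.01, 0.05, 0.1}). Raw pairwise θ may be slightly negative for
effectively identical populations; numeric output keeps the raw value,
and the distance-matrix view clamps at 0 before feeding MDS or NJ.

## Ordination and trees

PCA operates on the populations × (locus, allele) frequency matrix over
the union allele universe, columns centred but not scaled by default —
scaling is exposed as a flag since frequency columns are already
commensurable; components come from an SVD with a fixed sign convention
(largest-magnitude loading positive). MDS is classical Torgerson
double-centring of squared distances; negative eigenvalues (departures
from Euclidean realizability) are truncated to zero. Singular values
and eigenvalues below a relative 10⁻⁹/10⁻¹² are treated as exact zeros
so degenerate configurations produce exactly-zero trailing coordinates.

Neighbor-joining follows Saitou–Nei: join the pair minimizing
Q_ij = (r−2)d_ij − R_i − R_j, with limb lengths from the standard
formulas and a final three-point join. Tie-breaks are lexicographic on
labels everywhere, making output byte-reproducible. Negative limb
estimates are clamped to zero with the deficit shifted to the sibling
limb (the standard practical fix); raw values are retained on the edges.
On additive inputs the reconstruction is exact (path-length matrix
equals the input to 10⁻⁹ on random 6-taxon trees).

## Synthetic data

The generators define the conditions every stochastic test runs under;
all are pure functions of (config, seed) via an explicit numpy
Generator, with no global state.

- `sample_genotypes(freqs, n, f_is, seed)`: per individual and locus,
  with probability F_is one allele is drawn and duplicated, else two
  independent draws — realized heterozygosity has expectation
  (1 − F_is)·He. Loci are simulated independently, matching the
  near-universal non-significance of STR LD after correction; the
  coupled-locus generator is the only dependence mechanism.
- `balding_nichols_freqs(ancestral, K, F_st, seed)`: per locus and
  population a Dirichlet(p·(1−F)/F) draw around the ancestral vector,
  giving E[x] = p and Var[x] = F·p(1−p). Draws are floored at 10⁻¹²
  and renormalized, since tiny Dirichlet concentrations can underflow
  to exact zeros.
- `linked_pair(freqs, n, coupling, seed)`: locus B copies locus A's
  genotype with probability `coupling`, else is drawn independently —
  coupling 0 is exact independence, 1 a perfect duplicate.

The packaged reference table anchors the simulators to a realistic
forensic panel: 20 loci, 9–24 alleles each including microvariants,
n = 2 000. It ships as CSV with SHA-256 checksums verified at load.

What the simulations do *not* emulate: genotyping error and allelic
dropout, mutation (no stepwise-mutation model), family structure, and
real reference-population frequencies. Passing calibrations therefore
show the *machinery* is correct under its stated models, not that any
particular pair of real populations is or is not differentiated.

## Problem sizes and calibration conditions

Calibration tests use: HWE type-I error from 500 replicates of n = 200
at the 7-allele TPOX locus with 2 000 Monte-Carlo draws each (band
0.05 ± 0.02, ~2 binomial standard errors); LD type-I from 500
replicates of n = 100 with 199 permutations each; θ recovery as the
mean over 50 replicates of K = 4 populations × 20 loci × n = 200 at
F_ST = 0.05 (band [0.03, 0.07]); the 14-population clustering check
over 50 seeded replicates (3 populations at F = 0.005, 11 at F = 0.05,
D_A + NJ, criterion: the three low-divergence leaves form a connected
subtree in ≥ 90%). The acceptance script raises the two type-I
calibrations to 1 500 replicates so that binomial noise (SE ≈ 0.006)
stays well inside the reported band for any seed.

## Known limitations

- The frequency-based θ omits the genotypic heterozygosity component of
  the full Weir–Cockerham estimator; with genotype-level data for all
  populations the full estimator would be preferable.
- HWE enumeration is exhaustive, not network-pruned; it is intended for
  small conditionings (the property-test regime), with Monte-Carlo as
  the workhorse at panel scale.
- Exact and permutation tests are conservative by discreteness; at
  desk-scale permutation counts the granularity of p is 1/(N+1).
- GenePop export encodes microvariants via codes ≥ 900 recorded in the
  title line; files from other tools using different microvariant
  conventions are read back correctly only if they follow the same
  convention or use plain integer codes.
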