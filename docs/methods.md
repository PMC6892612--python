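# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Diallel design and in-silico hybrids

Founders are homozygous diploids, so an F1 hybrid's genotype is determined:
homozygous where the parents agree, heterozygous where they differ.  Three
cross schemes are supported: the full N² matrix (ordered pairs; reciprocal
hybrids are treated downstream as replicate constructions of the same
unordered cross, since with homozygous parents they are genetically
identical), the C(N,2) half matrix, and the half matrix plus the N
self-cross diagonal.  The full matrix of 55 parents yields 3025 hybrids
(2970 heterozygous + 55 homozygous); the half matrix plus diagonal of 34
parents yields the 595-hybrid association panel.

A useful identity of the half-matrix-plus-diagonal scheme: each parent
contributes one allele copy to each of its N−1 crosses and two to its
self-cross, i.e. N+1 copies of 2·(N(N−1)/2 + N) = N(N+1) total, so the
hybrid-panel allele frequency of every site equals its founder-sample
frequency exactly.  A variant carried homozygously by k founders has panel
MAF k/N regardless of its frequency in the source population the founders
were sampled from — the "boost" that makes low-frequency variants mappable.

**Site filters.** Before hybrid synthesis, sites with any missing call, any
heterozygous founder call, or no polymorphism across the panel are removed
(each counted under one reason, in that priority order).  Long-range LD
artifacts — with few founders, distant sites often share an identical
genotype column by chance — are pruned by grouping sites into perfect-LD
classes (identical founder columns), splitting each class into haplotype
blocks of consecutive sites at most `max_block_gap` apart (default 25 kb)
on one chromosome, and keeping only the first two blocks (genomic order) of
any class spanning more than two.  The block-gap default is a judgment
call; the exact block definition is configurable because no canonical one
exists for this filter.

## Combining abilities and heritability

For one condition, with z_ij the median phenotype of the heterozygous cross
i×j (reciprocals averaged) over the C(N,2) half diallel:

- μ = mean of the z_ij; z̄_i· = mean over the N−1 crosses involving i
- ĝ_i = (N−1)/(N−2) · (z̄_i· − μ); Σᵢ ĝ_i = 0 to numerical tolerance
- ŝ_ij = z_ij − ĝ_i − ĝ_j − μ

Homozygous diagonal hybrids are excluded from estimation; their model
prediction μ + 2ĝ_i is reported by `expected_phenotypes`, whose Pearson
correlation with observed values is exactly 1 on the heterozygous subset
(an algebraic identity) and drops below 1 when inbred diagonals deviate.

Error terms, with σ²(z_ij) the replicate variance of cross ij and n its
replicate count:

- e_gi = (N−1)·σ̄²_i / (n·N·(N−2)), σ̄²_i the mean replicate variance over
  parent i's crosses
- e_sij = (N−3)·σ²(z_ij) / (n·(N−1))
- σ²e = mean over crosses of σ²(z_ij)/n

σ²e treats the cross median as a mean of n replicates.  For Gaussian noise
the sampling variance of a median of 6 is ~1.57× that of the mean, so σ²e
is a mild underestimate; with realistic replicate noise (a few percent of
the genetic variance) the bias on h² is well under the tolerances used in
the recovery tests.  The per-cross covariance term sometimes added to the
within-cross variance expansion is not recoverable from replicate data of a
single hybrid and is deliberately replaced by the empirical replicate
variance.

Variance components use n−1 denominators: σ²A = Var(ĝ_i + ĝ_j) over
crosses, σ²SCA = Var(ŝ_ij).  Then h² = σ²A/(σ²A+σ²SCA+σ²e) and
H² = (σ²A+σ²SCA)/(σ²A+σ²SCA+σ²e), both clipped to [0, 1]; zero total
variance yields NaN with a warning.  Estimation noise in ĝ inflates σ²A
slightly at small N; at N = 30 with 6 replicates the mean bias on h² is
about −0.03 (recovery tests bound it at 0.08).

`heritability_calibration` condenses a multi-condition heritability table
into means, ranges, the mean non-additive share H²−h², and the Pearson
correlation between H² and h² across conditions — the summary one computes
when feeding the pipeline a real per-condition growth-ratio table.

## Inheritance-mode classification

P1 is the less fit parent (inputs are relabeled if needed; exact phenotype
ties are ordered by sd so the call never depends on argument order) and
MPV = (P1+P2)/2.  With w1 = σP1+σHyb, wm = (σP1+σP2)/2+σHyb, w2 = σP2+σHyb,
the six cut points

    P1−w1, P1+w1, MPV−wm, MPV+wm, P2−w2, P2+w2

tile the axis into underdominance / dominance-P1 / partial-dominance-P1 /
additivity / partial-dominance-P2 / dominance-P2 / overdominance.  The call
is the index of the first cut point exceeding the hybrid value (lower bound
inclusive, upper exclusive), which guarantees exactly one mode per input,
monotonicity in the hybrid value, and determinism when large sds make
nominal bands overlap — overlapping bands are resolved in listed order.
The seven-way call is attempted only when P1+σP1 < P2−σP2; otherwise only
escape from the parental range (over/underdominance) is callable and
everything else is `unclassified`.  The sds are replicate standard
deviations (hybrids n=6, parents n=54), not standard errors.  The mode
describes the hybrid's phenotype relative to its parents; it is not a
locus-level dominance inference.

## Mixed-model association

Genotypes: additive = minor-allele dosage (minor defined within the hybrid
panel, ties toward the alt allele), overdominant = heterozygosity
indicator.  Kinship K = ZZᵀ/m over standardized dosage columns of all
chromosomes except the tested site's (LOCO), rescaled to mean diagonal 1;
kinship always derives from the additive dosages, whichever encoding is
being tested.

Per (trait, chromosome) the null model y = μ + u + ε with
Var = σ²(h·K + (1−h)·I) is profiled by maximum likelihood over the variance
ratio h on the eigenbasis of the LOCO kinship, using a vectorized 65-point
grid on [0, 0.99].  The grid keeps every scan — observed or permuted —
procedurally identical (preserving exchangeability for the permutation
threshold) and is ample resolution for p-values; when K = I the likelihood
is flat in h and the site test reduces *exactly* to the OLS t-test, which
the oracle tests verify to 1e-8.  Each site then gets a closed-form GLS
slope and a two-sided t-test on n−2 df.  Monomorphic sites return β = 0,
p = 1, flagged.  At small panel sizes the fitted-h plug-in makes the test
mildly conservative (~4.4% of null p-values below 0.05 at n = 595); the
permutation threshold self-calibrates against this because observed and
permuted scans share the procedure.

**Permutation threshold.** Phenotypes are shuffled uniformly across hybrids
(no stratification), the scan re-run, and the genome-wide minimum p
recorded per permutation; the threshold is the ⌈α·n_perm⌉-th smallest
minimum (5th of 100 at α = 0.05), the min-p family-wise procedure.  The
alternative reading — the ⌈α·n_perm⌉-th smallest of *all* pooled permuted
p-values — is available as `method="pooled"`.  Permutations run per
(condition, encoding).

**Per-site summaries.** Cohen's d = (x̄₁ − x̄₂)/sdPooled with
sdPooled = √((sd₁²+sd₂²)/2); group 1 is always the heterozygotes, group 2
the major-allele homozygotes (additive; the larger, hence better powered,
homozygote class) or all homozygotes (overdominant).  Variance explained is
the squared Pearson correlation between genotype code and transformed
phenotype — encoding-agnostic, and exact for a single-site model.  The
MAF-enrichment summary classifies significant sites by *source-population*
MAF (low < 0.05, rare < 0.01), compares variance explained and |d| between
low-frequency and common classes with two-sided Mann–Whitney tests, and
reports the panel-vs-source MAF table.

## Phenotypes

Growth ratios are condition colony size / control colony size per
replicate (non-positive or missing controls give missing ratios).  The
phenotype is the replicate median (robust to pinning defects), with the
n−1-denominator sd and count retained.  The inverse normal transform maps
the value of average-rank r among n to Φ⁻¹((r−0.5)/n); the symmetric 0.5
offset keeps outputs finite and the transform monotone.  The transform is
applied over exactly the individuals entering each analysis.

## Synthetic data

`simulate_founders` draws, per site, a spectrum bin by weight and then a
carrier count k (founders are homozygous, so founder MAF = k/N) uniformly
among the counts achievable inside that bin; bins containing no achievable
count are renormalized away, every site keeps at least one carrier, and a
spectrum lying entirely below 1/(2N) raises.  The default spectrum puts
92.7% of mass below MAF 0.05, mimicking a large natural isolate collection
heavily skewed toward rare alleles.  The continuous bin draw is recorded as
`maf_source` — the variant's frequency in the notional source population —
while the realized founder MAF is the boosted panel-side quantity.  Sites
are placed uniformly on 16 chromosomes (the yeast karyotype) so LOCO
kinship has material to work with.

Genotypic values follow the classical parameterization: hom-major +a,
hom-minor −a, heterozygote d, summed over causal sites.  `d = 0` additive,
`|d| = |a|` complete dominance (a configurable fraction of causal sites),
`|d| > |a|` over/underdominance (factor 1.5–3).  Ground-truth GCA/SCA come
from exhaustively evaluating noiseless genotypic values over the half
diallel and applying the estimators above; for additive models this reduces
to ĝ_i = (p_i − p̄)/2 with p_i the parent's homozygous value, and true SCA
is identically zero.

Colony replicates are baseline 1.0 + genotypic value + Gaussian noise of
sd `env_sd` on the growth-ratio scale (a Student-t(3) alternative with
matched scale exercises the median's robustness), 6 replicates per hybrid
and 54 per parent by default.  The noise magnitude of real colony growth
ratios is not pinned by any published value; `env_sd` defaults to 0.05,
a few percent of a typical growth ratio, and is a free parameter.

Not emulated: linkage disequilibrium decay and recombination (founder
columns are independent draws), founder population structure, plate/spatial
effects, inbreeding depression of diagonal hybrids, and colony-image
quantification (the pipeline starts from size or ratio tables).  Passing
tests therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to structured real-data artifacts.

## Problem sizes and numerical choices

The test suite exercises the full study-scale *designs* (55- and 34-parent
enumerations are exact and instant) while simulation-backed checks use
panels the estimators' asymptotics are already stable at: heritability
recovery at N = 20–30 founders × 30 seeds, FWER calibration at 595 hybrids
× 2000 sites × 200 null scans × 100 permutations (the scanner precomputes
eigendecompositions and rotated genotypes once per panel, so a permutation
costs three matrix-vector products per chromosome), null-uniformity at
10,000 near-independent site-tests.  Degenerate inputs are defined, not
fatal: constant phenotypes give NaN heritabilities and threshold 1,
single-replicate data give σ²e = 0 with a warning, monomorphic sites give
p = 1.  All stochastic stages take explicit integer seeds and are
bit-reproducible.
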