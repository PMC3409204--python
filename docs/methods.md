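# Methods

This note records the statistical model behind `pathrank`, the numerical
conventions the implementation fixes, and what the simulation-based
tests do and do not establish.

## The competitive null and the scaled-rank device

For a study of K genes with association p-values `p_1..p_K`, the
competitive null hypothesis for a pathway S of size L states that
membership in S is independent of the association signal. Under that
null, the scaled ranks `u_k = rank(p_k)/K` of the pathway genes are a
uniform draw of L values without replacement from the grid
{1/K, ..., 1} — regardless of the marginal distribution of the
p-values, and hence regardless of study-wide inflation that shifts all
genes together. Every test in the package consumes these ranks (GSEA
also weights by the −ln p magnitudes but keeps rank-permutation
calibration), so all of them are exactly calibrated conditionally on the
observed universe, to Monte-Carlo accuracy of their null schemes.

Ties in p-values are broken by input order (ordinal ranking), so the
rank vector is always an exact permutation of the grid. Ties have
probability zero for continuous statistics; the ordinal rule simply
keeps the downstream products and order statistics well defined in
edge cases (e.g. monomorphic SNPs all assigned p = 1). A consequence
worth noting: the scaled-rank universe is the *same* fixed grid for
every data set, which is what lets the study driver reuse permutation
nulls across replicates (below).

## Null-calibration schemes

Three schemes are used, recorded with every result:

* **analytic** — FM against χ²(2L); TSM against N(0, v(L)) with
  v(L) = 1/L from the large-sample theory of the tail strength
  statistic. The χ² reference is exact for continuous-uniform inputs
  and remains accurate for the discrete ranks at K = 20,000; the normal
  TSM reference is known to be anti-conservative in variance for small
  L — simulation of the exact TS distribution gives one-sided 5%
  rejection rates of ≈0.017/0.030/0.034 at L = 20/60/100 — so the
  normal mode is kept deliberately as the conservative variant it is.
* **gene-label permutation** — draw L of the K scaled ranks without
  replacement B times (default B = 1000). Permutation p-values use the
  add-one convention (1 + c)/(1 + B): never zero, lower bound
  1/(B + 1).
* **empirical uniform** — replace the discrete rank draws with L iid
  Uniform(0,1) values (TSM_E with R = 100,000 draws by default; ARTP_E
  with B = 1000 replicate vectors). The continuous approximation to the
  discrete null is excellent at the K of interest and makes the null
  depend only on L, hence cacheable.

## ARTP and Ge's single-level reduction

The rank truncated product W(j) = u₍₁₎···u₍ⱼ₎ concentrates on the j
strongest pathway genes; ARTP scans every truncation point j = 1..L and
takes the one minimising the estimated p-value. Estimating the p-value
of an adaptively selected minimum naively requires a second, nested
permutation layer. Ge's algorithm avoids this: all B+1 replicates
(observed plus B null draws) are processed identically — each replicate
b gets, for every j, the pooled p̂ⱼ(b) = #{b′ : W(j)(b′) ≤ W(j)(b)}/(B+1)
counted over all replicates including itself, its ARTP statistic is
minⱼ p̂ⱼ(b), and the final p-value is the pooled proportion of replicates
whose statistic is at most the observed one. Pooling with
self-inclusion keeps observed and null replicates exchangeable, which
is the property the reduction rests on. The selected truncation point
ĵ is reported; ties take the smallest j (the most parsimonious
truncation, and deterministic).

With the truncation set restricted to {L}, the scheme collapses exactly
to Fisher's permutation test (W(L) is a monotone transform of T), which
the test suite asserts under shared replicate draws, and the full
scheme is checked against a naive two-level nested-permutation oracle
at small size.

## GSEA conventions

Gene statistics are t_k = −ln p_k, ranked decreasing (numerically the
most stable choice among the common transforms). The running sum gains
|t|^w/N_R at pathway hits (w = 1 fixed; N_R the sum of hit weights) and
loses 1/(K − L) at misses; the enrichment score is the *signed* maximum
of the walk — a one-sided, enrichment-at-top test, matching the
competitive (not depletion) question. Because hit increments are
non-negative, the walk's maximum is attained at a hit, so null scores
for B random gene subsets are computed from the L hit positions alone
(O(BL) instead of O(BK)); the test suite verifies this kernel against
the explicit O(K) running sum. If every pathway gene has p = 1 (all
weights zero, N_R = 0) the hit increments fall back to equal weights
1/L. The log base is immaterial: N_R-normalisation cancels any constant
factor.

## The GWAS generator

The simulator reproduces a deliberately idealised quantitative-trait
GWAS: N = 100 individuals, K = 20,000 SNPs with one SNP per gene, MAF
q_j ~ Uniform(0, 0.5), genotypes iid within column under Hardy–Weinberg
((1−q)², 2q(1−q), q²), M effect SNPs with β ~ N(0, σ²), additive
phenotype y = Gβ, and per-SNP two-sided slope t-tests (N−2 df). The
phenotype carries no separate environmental noise term by default: with
M ≥ 50 effect SNPs the other effect loci already supply a polygenic
noise background for each tested SNP, and `noise_sd` is exposed for
sensitivity analysis. Null scenarios draw pathway membership and effect
assignment independently; alternative scenarios give round(π·L) pathway
genes effects of variance σ₁² and place the remaining M − round(π·L)
effects outside the pathway with variance σ₂² < σ₁². All draws are
without replacement.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, multi-SNP genes, case-control traits, population structure,
genotyping error. Calibration and power results therefore speak to the
rank machinery itself, not to LD-induced correlation between gene
statistics — the main caveat when extrapolating to real GWAS, where
mapping SNPs to genes and the permutation adjustment (below) absorb
only part of that structure.

## Study driver, seeding and caching

Replicate r of scenario i under master seed s uses the generator stream
`default_rng([s, i, r])`, so any cell of a grid is reproducible in
isolation and streams never collide. Rejection rates are reported with
binomial standard errors; grid summaries are unweighted means across
scenarios (each scenario counts equally).

The driver caches every null object that depends only on the pathway
size: the TSM_E null (per L), the ARTP_E null (per L) and — because the
rank universe is the fixed grid — the ARTP gene-label permutation null
(per K, L). Cached ARTP nulls omit the observed replicate from the null
replicates' own p̂ counts, a deviation of at most 1/(B+1) per p̂ from the
exact pooled scheme (the exact scheme is used by `artp_pvalue` and in
the oracle tests); with B = 1000 this is far below Monte-Carlo noise.
Reusing one null across replicates correlates their rejection
indicators slightly, which inflates the variance of a pooled rate
estimate but not its expectation.

Problem sizes used by the shipped study runs: the acceptance script
runs the 27-scenario null grid at 200 replicates per scenario (pooled
SE ≈ 0.003) and the power scenarios at 300 replicates (SE ≤ 0.03); the
test suite uses 75 and 100–150 replicates respectively, with acceptance
bands widened to 3 binomial SEs at the count actually used.

## Real-data front-end

SNPs are mapped to the closest gene whose coding start (strand-aware:
`start` on +, `end` on −) lies within a window, 10 kb by default and
always configurable — equidistant ties go to the lexicographically
smaller gene id. A gene's statistic is the minimum p over its SNPs,
which favours SNP-rich genes; the phenotype-permutation adjustment
p̃_g = (1 + #{b : min-p_g(b) ≤ min-p_g})/(1 + B) recalibrates each gene
against its own permutation distribution and removes that size bias
(the suite checks that 10-SNP and 1-SNP genes both come out uniform
under a null phenotype). The permutation machinery consumes a
caller-supplied SNP-level p-value matrix; the package does not re-run
association on raw genotypes. Coordinates are 1-based inclusive in TSV
input; BED input is converted on read.

## Known limitations

* No multiple-testing correction across pathways is applied or
  implied; reported p-values are nominal.
* The hypergeometric variant with a fixed p-value threshold inherits
  the discreteness of small significant lists and is conservative; the
  top-2000 list is the calibrated default.
* Power figures from the simulator transfer to real data only up to
  the idealisations listed above; in particular independence between
  gene statistics makes every permutation null slightly optimistic
  relative to LD-correlated data.
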