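# Methods

## Model and estimators

Genotype frequencies at a biallelic locus are parameterized by the
inbreeding coefficient f: AA p²(1−f)+pf, Aa 2pq(1−f), aa q²(1−f)+qf. The
parameterization covers inbreeding, assortative mating and structure alike;
what distinguishes them is *which loci* are affected.

**Single locus.** The allele frequency is invariant under all of these
processes, so p̂ = (2n₂+n₁)/2n is plugged in and the profile likelihood
maximized over f alone. The estimator reproduces the observed genotype
proportions exactly (two free parameters against two degrees of freedom of
the trinomial), which has two useful consequences: the interior MLE is the
closed form f̂ = 1 − n₁/(2np̂q̂), and the estimate is automatically
feasible — clipping to [−min(p̂,q̂)/max(p̂,q̂), 1] only guards numerical
edge cases. Estimates may be negative; heterozygote *excess* (negative f)
is as informative as deficit and arises systematically from finite samples
and admixture (below).

**Multiple loci.** For M LD-pruned SNPs a common f_M maximizes the product
of per-locus multinomial likelihoods, each with its own plugged-in p̂ᵢ. The
joint log-likelihood is a sum of logarithms of functions affine in f, hence
concave; bounded Brent search (tolerance 1e-8) on the intersection of
per-locus feasible ranges finds the global optimum, with ties broken toward
zero. f_M closely tracks the mean of single-locus estimates when the loci
have comparable frequencies (asserted within ±0.005 in the tests).

## The resampling test

The null hypothesis is "no trait-specific mating signal", not "no
confounding": structure, relatedness and finite-sample bias are all allowed
under the null and must not produce rejections. The test therefore compares
the trait set's f_M with B re-estimates on random SNP sets matched to it in
size and minor-allele frequency (bin width 0.01 by default; an empty bin is
widened once to its neighbors, then errors). Matching is without
replacement within a resample and independent across resamples. The
empirical p uses the +1 convention, p = (1+#{null ≥ obs})/(B+1), making
1/(B+1) the attainable floor (0.000999 at the conventional B = 1000).
Matching bins scarcest-first so a tight bin is never stranded by an earlier
pick. If the pool secretly contains trait loci the null shifts upward and
the test becomes conservative — the safe direction.

Single-locus comparisons (Welch t and two-sample KS on the per-locus f̂
vectors of the trait set versus one matched set) complement the global test.

## The LD-product regression

One generation of assortative mating induces gametic disequilibrium between
unlinked trait loci with magnitude proportional to βᵢβⱼ; ancestry structure
induces D proportional to the product of the loci's loadings on the leading
genetic PCs. D is estimated phase-free by the composite (Burrows-type)
covariance estimator D̂ = cov(gᵢ,gⱼ)/2, consistent for gametic D under
random union of gametes, and regressed (OLS with intercept) on
(βᵢβⱼ, load1ᵢ·load1ⱼ, load2ᵢ·load2ⱼ) over all cross-chromosome trait-SNP
pairs. Effect sizes come from univariate OLS of the phenotype on dosage;
loadings from PCA of the dosage matrix standardized by (g−2p̂)/√(2p̂q̂),
with the largest-magnitude loading of each component forced positive for
reproducibility. Loadings are computed on the full post-QC matrix (not the
trait SNPs alone) and all cross-chromosome pairs are used.

## Quality control

Defaults follow GWAS convention: variants dropped at call rate < 0.95,
MAF < 0.01 or exact-HWE P < 5e-7 (all strict inequalities, so values
exactly at a threshold survive); samples dropped at missing rate > 0.1. The
HWE test is the exact conditional enumeration of heterozygote counts given
the allele counts (the SNP exact test), with a chi-square option. LD
pruning slides a 50-variant window stepping by 5 and greedily drops one
member of any pair with r² > 0.1 — the lower-MAF member by default, or a
seeded random member, since random retention matters when heterozygosity
itself is the quantity under study. Kinship uses the standardized-dosage
GRM A_jk = (1/m)Σ(g_ij−2pᵢ)(g_ik−2pᵢ)/(2pᵢqᵢ); exclusion above 0.025 is
greedy, removing the most-connected individual first. PC-outlier removal
(mean ± 6 SD on PC1/PC2 by default) is available but off by default in the
pipeline.

Two GRM facts matter at simulation scale: the off-diagonal expectation is
−1/(n−1) (in-sample frequencies center the rows), and its noise SD is
≈ 1/√m. With panels of only ~10³ SNPs the 0.025 cutoff sits inside the
noise band and greedy exclusion can cascade; the kinship stage is therefore
sensible only with genome-scale panels (the real-data regime) and is
switchable in the pipeline config.

## The simulator and what it does (not) emulate

`simulate_hw_genotypes` draws genotypes directly from the f-parameterized
class frequencies — the ground truth for estimator recovery.
`simulate_assortative_population` is a forward model: founders in HWE at
MAFs uniform in a range (default 0.1–0.5), an additive trait
y = Σβg + e with equal positive β at trait loci and environmental variance
set so genetic/total = h² (default 0.8, the classic tall-trait
full-sib estimate), mates paired by phenotype rank, Mendelian transmission,
constant population size. Mate matching adds Gaussian noise of variance
σ²_P(1/ρ² − 1) to ONE side's ranking score so the realized spousal
correlation approximates the target ρ (default 0.4, the scale of reported
spouse-height correlations); ρ = 0 degenerates to random pairing and a
realized deviation beyond ±0.05 raises a warning, not an error. Under this
design the offspring's expected per-trait-locus f is ρh²/(2m): the spousal
per-locus genotype correlation is ρh²/m and transmitted gametes carry a
quarter of the genotype covariance.

`simulate_structured_population` provides the two structure regimes with
closed-form expectations: pooling subpopulations (labels shared across
loci) gives the Wahlund deficit F = var(p)/(p̄q̄); an F1 cross gives the
mirror-image excess 1 − (p₁q₂+p₂q₁)/(2p̄q̄).

Deliberately absent: linkage and recombination maps (loci are unlinked by
construction; chromosome labels are assigned round-robin over 1–22 purely
so cross-chromosome pairs exist), mutation, selection, migration, realistic
site-frequency spectra, genotyping error, and multi-generation demographic
change. Passing tests therefore demonstrate correctness of the estimators
and calibration of the tests under the assumed independence structure; they
do not probe robustness to LD leakage between "independent" SNPs or to
array artifacts, which real data would add.

## Problem sizes and numerical choices

The validation suite uses scales at which each analytic expectation is
resolvable: 10⁵ draws for genotype-frequency checks; n = 2,000 × M = 200
for recovery at f = 0.05 (SE ≈ 0.0016); n = 50 × 5,000 loci for the
−1/(2N−1) = −0.0101 finite-sample mean; n = 5,000 × 500 loci for the ±0.16
structure closed forms; 200 replicate cohorts (n = 300, 50 trait SNPs,
1,500-SNP pool, B = 200) per arm for type-I calibration; and 20 replicates
of n = 10,000 offspring with a 2,000-SNP pool for detection power and the
LD-regression sign. Trait-SNP MAFs in the type-I cohorts are drawn from a
range interior to the pool's (0.15–0.45 vs 0.1–0.5): with a pool of only
1,500 SNPs, a boundary trait SNP can otherwise land in a frequency bin the
pool cannot fill even after widening — a small-pool artifact that
genome-scale pools do not have.

Other numerical conventions: dosage codes are int8 with −1 as missing;
missing calls are dropped per locus for counting, mean-imputed only inside
the LD-pruning correlation, and zero-filled after standardization for
GRM/PCA; monomorphic loci are errors in estimation, convention p = 1 in the
HWE test, and skipped with a warning in GRM/PCA; after QC allele 1 is
re-oriented to the minor allele (estimation is invariant; matching and
reporting read MAF directly). All randomness flows through
`numpy.random.default_rng` seeds recorded in outputs; equal seeds give
byte-identical results.

## Known limitations

- The multi-locus likelihood treats loci as independent; residual LD after
  pruning biases the effective number of loci and hence the resampling
  null's spread (mitigated, not removed, by r² < 0.1).
- Effect sizes in the D regression are estimated in-sample, so the
  regression inherits their sampling noise; no measurement-error
  correction is applied.
- Age adjustment of spousal correlations is a single pooled OLS over all
  paired individuals; no per-sex adjustment is attempted.
- The exact HWE p-value is conditional on allele counts; with extreme
  sample sizes the enumeration is O(n) per locus, which is fine to ~10⁶.
- Empirical p-values cannot fall below 1/(B+1); claims beyond that floor
  need larger B, not extrapolation.
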