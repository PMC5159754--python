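# Methods

This note documents the statistical models behind each metric, the
parameter choices, the simulator's scope, and the numerical decisions a
maintainer should know about.

## Summary-statistics model

Every metric consumes per-cohort tables of per-SNP records
(id, chromosome, position, effect allele a1, other allele a2, effect-allele
frequency, effect b, standard error σ, sample size n). Records failing
basic invariants (σ ≤ 0, frequency outside [0,1], invalid alleles) are
dropped at load time and counted in a report. Cross-cohort comparisons
first harmonise alleles to the first cohort's effect allele: swapped pairs
flip the effect sign and replace p by 1−p; strand flips (allele
complements) are resolved when unambiguous; palindromic A/T and C/G
markers are dropped by default because their orientation cannot be decided
from frequency near 0.5. Within one simulation all cohorts report on the
same strand, so the pipelines that compare a simulated pair keep
palindromic markers (`drop_ambiguous=False`) to use all loci.

"Markers in linkage equilibrium" are approximated, in the absence of
genotype data, by distance thinning: markers are visited in seeded random
order and kept while no accepted marker on the same chromosome lies within
`min_gap_bp` (default 100 kb), up to `target_m` (default 30 000). On
unlinked simulated markers this reduces to uniform subsampling; on real
data it is a proxy, not an LD computation, and callers with genotypes
should substitute a proper LD-pruned list.

## Fst and the cartographer

Fst uses a Hudson-type estimator combined across SNPs as a ratio of
averages with an unbiased finite-sample correction, p(1−p)/(2n−1), per
population. Per-SNP numerators are deliberately left unclamped (negative
values average out; clamping each SNP would bias the ratio upward); only
the final ratio is clamped to [0,1], and the raw value is available for
diagnostics — on two samples of the same population it is slightly
negative. All Fst values for one cohort profile are computed on one shared
SNP set so the three distances are comparable.

The cartographer convention is that *squared* Euclidean distance in the
2-D plane equals Fst, consistent with the linear relationship between Fst
and squared principal-component distance. The three reference populations
are embedded by classical metric MDS (double-centred squared-distance
matrix, top two eigenpairs, negative eigenvalues clipped); each cohort is
then placed by least-squares trilateration from its three Fst values,
linearised by subtracting the first anchor's circle equation, with the
residual of the quadratic objective reported as a misfit diagnostic.
Exactly three anchors are supported; more are rejected rather than
silently generalised to a higher-dimensional embedding. The outlier scan
flags cohorts whose Fst to a pooled (sample-size-weighted) reference
exceeds 0.005 by default, the scale below which typical within-continent
cohorts fall.

## Meta-PCA

The cohorts × SNPs frequency matrix is restricted to SNPs present in every
cohort (no imputation — frequencies are cheap and the intersection is
large in practice) with pooled MAF ≥ 0.01 by default. Columns are centred;
the default `center_scale` mode also divides by √(p̄(1−p̄)), the frequency
analogue of genotype standardisation (`center` is exposed because the
appropriate scaling is a judgement call). Coordinates are left singular
vectors × singular values. Like any PCA, the projection depends on which
cohorts (and reference rows) are included; only determinism is guaranteed,
via a fixed sign convention (each component's largest-magnitude loading is
positive).

## λ_meta

Under the null (independent cohorts, same true effects),
Tᵢ = (b₁ᵢ−b₂ᵢ)²/(σ₁ᵢ²+σ₂ᵢ²) ~ χ²₁, and λ_meta = median(T)/median(χ²₁) has
expectation 1. The χ²₁ median is evaluated at full double precision
(0.45493642…), never the rounded 0.455. The theoretical SE comes from the
asymptotic variance of a sample median, 1/(4 m f(q)²) with f the χ²₁
density at its median, rescaled by 1/median(χ²₁): 0.0135 at m = 30 000.
The all-pairs scan additionally standardises each pair's λ by the
empirical across-pair mean and SD, since real consortium data show more
spread than theory (protocol heterogeneity); both z scores are reported
and flags use Bonferroni over the number of pairs.

Overlap model: if two cohorts share nₒ effective individuals, the two
effect estimates correlate with γ = nₒ/√(n₁n₂), so
Var(b₁−b₂) = σ₁²+σ₂²−2γσ₁σ₂ and, with σ² ∝ 1/n,
E[λ] ≈ 1 − γ·2√(n₁n₂)/(n₁+n₂). Inverting gives
γ̂ = (1−λ)(n₁+n₂)/(2√(n₁n₂)) and n̂ₒ = (1−λ)(n₁+n₂)/2. Negative γ̂
(λ > 1) is reported as heterogeneity, with no overlap count. The deflation
for a fixed shared-individual count depends only on n₁+n₂; for a fixed
correlation γ it is maximal at n₁ = n₂, which is the sense in which equal
cohort sizes maximise detection power. The transform is valid for
quantitative traits; for case–control studies the case/control ratio
breaks the σ² ∝ 1/n premise and only the *presence* of overlap (λ < 1) is
interpretable — PPSR is the tool for counting. If input SEs were
genomic-control adjusted, λ_meta is deflated relative to unadjusted input;
the package annotates rather than un-corrects, since the GC factor is
usually unrecoverable from the table.

The frequency-mode variant replaces effect differences by
(p₁ᵢ−p₂ᵢ)²/(p₁ᵢ(1−p₁ᵢ)/2n₁ + p₂ᵢ(1−p₂ᵢ)/2n₂); markers monomorphic in both
cohorts carry no information and are excluded with a count.

An alternative overlap estimator — the direct Pearson correlation of the
two cohorts' effect estimates — is confounded by genetic architecture:
with non-zero heritability the shared true effects inflate it even with no
overlap, and the inflation grows with sample size. λ_meta is immune
because true effects cancel in b₁−b₂. The acceptance suite reproduces both
the inflation and the immunity.

## PPSR

Genotypes are standardised to (g−2p)/√(2p(1−p)) with *hub-supplied*
reference frequencies, not per-cohort frequencies — per-cohort
standardisation would bias cross-cohort coefficients. Standardisation is
required for the regression coefficient to live on the relationship scale
where first-degree relatives sit at 0.5. Missing dosages become 0 after
centring (mean imputation), so realistic missingness (~1%) shifts
coefficients only marginally instead of destroying matches. Scores are
x·W/√M, making coefficients M-free.

The all-pairs coefficients are computed as one matrix product of
row-centred score matrices; both regression directions are formed and
classification uses max(b_ij, b_ji), robust to one-sided variance
deflation from missingness. Thresholds: 0.95 for duplicates, 0.45 for
first-degree relatives.

Design calculation: an unrelated pair's coefficient is approximately
N(0, 1/K); a related pair with relationship ρ is N(ρ, (1−ρ²)/K). With
Bonferroni per-test level α/n_tests and one-sided normal tests, power 1−β
at threshold ρ needs K ≥ ((z₁₋α + z₁₋β√(1−ρ²))/ρ)², rounded up. With
488 587 090 pair tests, α = 0.01, β = 0.05 and ρ = 0.95 this gives K = 57.
The detection boundary implied by the design, z₁₋α/√K, is below ρ itself,
so classifying at b ≥ ρ is conservative — consistent with the observed
absence of false positives.

Decoding risk: an analyst knowing the weight matrix can least-squares
decode standardised genotypes from the K scores. We model the strongest
such attack — the minimum-norm solution x̂ = √M·s·W⁺ — rather than per-SNP
marginal regression, because it bounds the leakage: it is exact when
K ≥ M and recovers only the projection onto the K-dimensional weight span
when K < M, so accuracy grows with K/M. Reported as mean squared
correlation between decoded and true dosages per MAF bin
(<0.1, 0.1–0.3, 0.3–0.5). Keeping K/M small (e.g. 57/500 ≈ 0.11) keeps
per-SNP R² far below 1.

## Simulator

What it emulates: Balding–Nichols population differentiation (ancestral
frequency uniform on the MAF range, default 0.05–0.95; population
frequency Beta-distributed with variance F·p(1−p)); unlinked Binomial(2,p)
genotypes; polygenic quantitative phenotypes (iid normal effects on n_qtl
QTLs, default 1000, scaled so the genetic variance equals h² of a
unit-variance trait, using the population's expected dosage variance so
effects are shared across cohorts); exact sample overlap (genotype and
phenotype copied); first-degree relatives by gene-dropping one parental
allele with the other drawn from the population; shared control pools for
case–control designs; and per-SNP simple least-squares summary statistics
(the vectorised column-sum implementation is tested to 1e−10 against a
per-SNP regression loop).

What it does not emulate: linkage disequilibrium, imputation error,
genotyping-platform artifacts, case–control ascertainment, non-normal
effect-size distributions, and cryptic population substructure within a
cohort. Passing tests therefore demonstrate the statistics' behaviour
under their own assumptions, not robustness to those real-data
complications; the thinning step exists precisely because real data
violate linkage equilibrium.

Default experiment sizes follow the study design the metrics were built
around: 30 000 independent markers per pair, heritability on 1000 QTLs
(results with 100 QTLs are nearly identical), overlap designs with
n₁ = 1000 and n₂ up to 10 000, and 10 replicates per configuration for
the recovery experiments (20 for the null expectation, where only the mean
matters). The Monte-Carlo check of the λ null SD uses 10 000 replicates of
the 30 000-value median, which resolves the SD to ~1%.

## Numerical choices and degenerate inputs

- Monomorphic SNPs: GWAS records emitted with NaN effect/SE and excluded
  downstream; all-monomorphic Fst input raises (the denominator is zero);
  frequency-mode λ excludes per-SNP zero-variance markers with a count.
- Zero-variance PPS rows (e.g. all-missing individuals) are skipped and
  counted, not propagated as NaN matches.
- MDS eigenvalues below zero (non-Euclidean Fst matrices) are clipped;
  collinear reference vertices raise a degenerate-geometry error.
- Ties/sign conventions: meta-PCA components fix the largest-magnitude
  loading positive; thinning and weight generation are deterministic under
  their seeds; float formatting in writers uses 17 significant digits so
  write/read round trips are bit-exact.
- Seeds: every stochastic entry point takes an explicit seed (CLI default
  2016); the acceptance script derives independent sub-seeds from its
  single `--seed` via a master generator.

## Known limitations

- The λ→nₒ transform assumes quantitative traits and σ² ∝ 1/n; with
  genomic-control-adjusted or mixed-model SEs it underestimates overlap.
- The cartographer is 2-D with exactly three anchors; its placement
  depends on the chosen references, as does meta-PCA on the cohort set.
- Distance thinning is not LD pruning.
- PPSR classifies only duplicates and first-degree relatives; more distant
  relatedness is visible in the coefficients but not thresholded.
- PPSR genotype input is the delimited dosage-matrix format; VCF
  conversion is left to standard tools upstream.
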