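# Methods

## The model

A quantitative trait measured in two ancestry groups is treated as two
traits.  With phenotypes stacked population-1-first and one or more SNP
sets (components) indexed by k,

    V = Σ_k [ Vg1_k A11_k   C_k A12_k ]  +  [ Ve1 I    0    ]
            [ C_k A21_k   Vg2_k A22_k ]     [  0    Ve2 I   ]

where A_k is the genomic relationship matrix built from SNP set k over the
combined sample.  No individual belongs to both populations, so the
residual cross-population covariance is identically zero.  The
cross-population genetic correlation of component k is
r_g = C_k / sqrt(Vg1_k Vg2_k) and the SNP heritability of population p is
h² = Σ_k Vgp_k / (Σ_k Vgp_k + Vep).

Genotypes are standardized as z = (x − 2p)/sqrt(2p(1−p)).  Two modes:
**specific** standardizes each individual by its own population's allele
frequencies (within-population blocks centred near zero; the
cross-population block carries the genetic covariance), and **average**
uses pooled frequencies (frequency divergence then appears as positive
within-population and negative cross-population relatedness — the matrix
whose leading eigenvectors separate the populations and supply PC
covariates).  Frequencies are estimated from the analysis sample unless
supplied.  Missing genotypes become 0 after standardization with per-pair
SNP counts as divisors.

## AI-REML

The REML log-likelihood (constants dropped) is
−2logL = log|V| + log|X'V⁻¹X| + y'Py with
P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹.  Because V is linear in every parameter,
the score −½[tr(PV_i) − y'PV_iPy] and the average-information matrix
½ y'PV_iPV_jPy are exact.  Fixed effects enter only through their column
space; X is replaced by an orthonormal basis internally, which makes logL
invariant to reparameterization and quietly absorbs rank-deficient designs
(a covariate already spanned changes nothing).

Iteration: a full AI (Newton) step, halved up to five times if it leaves
the positive-definite region or decreases the likelihood; failing that, an
EM step for the variance components combined with a Levenberg-damped AI
step for the genetic covariances (an EM update is multiplicative in the
parameter and cannot move a covariance off zero, which is where it
starts).  Variance components are floored at 1e-6 of the phenotypic
variance; parameters pinned at the floor with an outward-pointing score
are held fixed that iteration (active set), and fits with pinned
components carry a boundary flag because their SEs are unreliable.  C is
unconstrained, so r̂_g may exceed 1 in small samples — that is a property
of the estimator, not an error.  Convergence requires |ΔlogL| < 1e-4 and
a maximum relative parameter change < 1e-4 (default cap 100 iterations;
non-convergence is flagged, never silent).  The sampling covariance of the
estimates is the inverse AI matrix at the optimum.

Starting values: the neutral default sets Vg_k = Vp/(2K), Ve = Vp/2,
C_k = 0 per population — deterministic and assumption-free.  A
Haseman–Elston warm start (`start="he"`; regressing phenotype
cross-products on the corresponding GRM blocks) is available and is used
by the pipeline drivers: it lands close enough to cut the iteration count
roughly in half at n ≈ 4000, where each iteration costs one Cholesky and
one triangular inversion of V.

P(r_g = 1) is a Wald test on the delta-method SE, matching the
estimate/SE/P reporting pattern; a profile-likelihood test would be a
config-level alternative but is not implemented.

## Sampling variance of r̂_g and the difference test

var(r̂_g) and cov(r̂_g1, r̂_g2) between two SNP sets are evaluated
term-by-term from the variance-component sampling covariance:

    var(r̂_g) = r_g² [ var(V̂g1)/(4Vg1²) + var(V̂g2)/(4Vg2²) + var(Ĉ)/C²
               + cov(V̂g1,V̂g2)/(2Vg1Vg2) − cov(V̂g1,Ĉ)/(Vg1C) − cov(V̂g2,Ĉ)/(Vg2C) ]

with the analogous nine-term bracket for the covariance between two sets
(coefficients 1/4 on variance×variance terms, 1/2 on variance×covariance
cross terms, 1 on the C×C term).  Both brackets are algebraically
identical to the generic delta method (gradient' Σ gradient with
∂r_g/∂Vg = −r_g/2Vg, ∂r_g/∂C = 1/sqrt(Vg1Vg2)); the test suite asserts
agreement to 1e-12, which pins down the transcription.  At C = 0 the
1/C² factors cancel analytically — var(r̂_g) → var(Ĉ)/(Vg1Vg2) — and the
code switches to that closed form rather than dividing by zero.
Parameters are replaced by their estimates throughout.  The difference
between two jointly fitted SNP sets is tested with
χ²(1) = (r̂_g1 − r̂_g2)² / [var(r̂_g1) + var(r̂_g2) − 2cov(r̂_g1, r̂_g2)].

## Stratification

Per-SNP F_ST uses Hudson's estimator by default,
[(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)] / [p1(1−p2) + p2(1−p1)],
with n counting sampled allele copies (2× diploid individuals), which is
the scale on which the sampling-error correction is right; Weir–Cockerham
is selectable.  Negative per-SNP values are retained — they are what makes
the estimator unbiased near zero, and ranking uses the raw values.  For a
genome-wide summary the package reports the ratio-of-sums combination
(Σnum/Σden), which is unbiased for the island-model F; the mean of per-SNP
ratios is biased downward ~15% at F = 0.1 because numerator and
denominator are correlated.

LD scores are windowed sums of bias-adjusted squared correlations,
r̃² = r² − (1−r²)/(n−2), window ±1000 kb by default, self term exactly 1.
LDCV is the two-value coefficient of variation |ℓ1 − ℓ2|/(√2·mean).

Binning is equal-count by rank (bin = rank·k // n, ties broken by SNP
index): quantile edges guarantee splittable occupancy where equal-width
bins would not, and rank assignment never produces empty bins.  Axis 1 is
the population-1 MAF; axis 2 is the population-2 frequency **of the same
allele** (unfolded, so a systematic shift is matched rather than folded
away); LD bins are nested within each frequency cell (per-cell quantiles),
crossed per population.  The F_ST configuration uses 125×125 frequency ×
4×4 LD bins (250,000 possible joint bins); the LDCV configuration
20×20 × 25×25.  Within each joint bin SNPs are sorted by the metric,
lower half → low group, upper half → high group; in odd bins the median
SNP is assigned by a seeded coin flip (the odd-bin randomization rule
generalized to any odd count), so group sizes differ by at most the
number of odd bins.

A known residual of this protocol, measured in this package's balance
simulations at 10⁶ SNPs: the high-F_ST group retains a systematic shift of
~1% of an SD in the population-2 folded MAF (population-1 MAF and both LD
scores balance to <0.2%).  Within a frequency cell F_ST is a deterministic
function of the residual |p1 − p2| spread, so sorting by F_ST inside the
cell necessarily tilts the population-2 frequencies; the effect is of
order bin-width and cannot be removed without more than 125 bins.  Users
comparing strata should treat the population-2 frequency profile as
matched to ~1%, not exactly.

## Summary-statistics branch

The association scan is covariate-adjusted least squares: covariates plus
intercept are projected out of phenotype and genotypes once (QR), then
per-SNP slope, SE and two-sided t-test P follow in closed form with the
correct residual degrees of freedom.  This is exact for unrelated samples,
which the simulator produces by construction; a sparse-GRM mixed model
would add nothing here.  Missing genotypes are mean-imputed per SNP;
monomorphic SNPs yield NaN rows.

Clumping is greedy and p-value-ordered (ties by position then id): the
best unassigned SNP below 5e-8 becomes a sentinel and absorbs unassigned
SNPs within ±1 Mb at r² > 0.01, computed from the analysis genotypes; a
second round with a 10 Mb window over round-1 sentinels removes residual
long-range LD.  Winner's curse is avoided by a split-sample design:
sentinels are selected in a discovery half and their effects re-estimated
in the disjoint half.

r_b corrects the attenuation of the naive Pearson correlation of noisy
effect estimates by subtracting the mean squared SE from each variance:

    r_b = cov(b̂_a, b̂_b) / sqrt[(var(b̂_a) − mean(se_a²)) (var(b̂_b) − mean(se_b²))]

valid when the two error sets are independent (disjoint samples; passing
identical summary statistics is rejected).  If noise exceeds signal the
corrected variance goes non-positive and r_b is reported as undefined
rather than clamped.  The SE is a delete-one jackknife over sentinels,
SE² = (k−1)/k Σ(r_(−j) − mean)².  Alleles are harmonized to a shared
effect allele with sign flips; A/T and C/G SNPs are retained (the
simulator has no strand ambiguity) — real-data users should filter them.

## The simulator and what it does not emulate

Allele frequencies follow the Balding–Nichols model: ancestral p uniform
on (0.05, 0.5) by default, each population's frequency
Beta(p(1−F)/F, (1−p)(1−F)/F), so E per-SNP F_ST equals the F parameter
(default 0.1, a continental-scale divergence).  LD is a latent-Gaussian
AR(1) threshold model in blocks (default 20 SNPs at ρ = 0.5, blocks
independent, 10 kb spacing): marginal frequencies are exact and adjacent
LD is tunable in closed form.  Causal effects (default 1000 of 5000 SNPs)
are bivariate normal with correlation rg_true on the standardized-genotype
scale (the GRM model's implicit scale; a per-allele option serves the
summary-statistics branch).  Genetic values are rescaled so the realized
h² equals its target exactly, and N(0, 1−h²) noise completes a
unit-variance phenotype.  Optional per-individual admixture mixes
haplotype-block sources for population 2 under a shared latent field
(LD-preserving); optional uniform missingness feeds the QC tests.  All
randomness flows through one seed with a documented stream order
(frequencies, genotypes, effects, phenotypes), so identical seeds give
byte-identical outputs.

Not emulated: coalescent haplotype structure, recombination-map LD decay,
selection, imputation error, relatedness beyond the admixture option, and
any LD between blocks.  Passing tests therefore certify the estimators
under the model's own assumptions — frequency divergence, tunable LD,
shared polygenic architecture — not robustness to real-data pathologies
such as uncorrected stratification or long-range LD.

One consequence worth knowing: because causal SNPs are a random subset of
the genotyped panel and LD is block-local, the SNP-tagged r_g estimated by
GREML coincides with the causal-effect correlation rg_true here; with real
LD differences between populations the tagged r_g is an attenuated
version of the causal one, which is part of what the stratified contrast
probes.

## Problem sizes and numerical choices

The test suite checks AI-REML against direct numerical maximization of the
same restricted likelihood on five tiny instances (30 per population, 100
SNPs, agreement ~1e-9, tolerance 1e-3), recovery at 2000 per population ×
5000 SNPs over 20 replicates, SE calibration over 200 replicates at 500
per population (empirical SD / mean analytic SE ≈ 0.96), difference-test
type-I error over 200 reduced replicates at 200 per population, and the
r_b machinery at its native summary level (500 sentinel pairs).  The
pipeline's desk-scale preset (2000 per population, 5000 SNPs, 1000 causal)
runs each driver in minutes on one core; the sentinel workflow preset uses
a sparser architecture (60–100 causal SNPs at h² ≈ 0.6–0.7) because
individually genome-wide-significant loci at desk-scale n require
concentrated effects.

Eigen-decompositions use LAPACK `syevr` with residual checks at 1e-8;
PCs are scaled by sqrt(eigenvalue) with the largest-magnitude loading
positive for reproducible covariate files.  GRM files store float32
(round-trip error <1e-6); PLINK BED round trips are bit-exact, with
genotypes counting the second BIM allele (dosage 2 ↔ bit pair 11).  The
relatedness pruner is greedy max-degree with lowest-index tie-break —
deterministic, and within one of optimal on small graphs by construction
of the tests.  The inverse-normal transform uses offset (rank − 0.5)/k
with average ranks for ties; outliers are removed before covariate
adjustment, matching the stated cleaning order.

## Known limitations

- AI-REML cost is O(n³) per iteration with dense GRMs; ~5000 combined
  samples is the comfortable desk-scale ceiling.
- SEs at variance-component boundaries (h² ≈ 0) are unreliable; fits carry
  a boundary flag there.
- The HWE exact test is applied to whatever sample it is given; pooling
  diverged populations triggers Wahlund-effect removals, so per-population
  QC is the right usage on structured data.
- The stratified split's residual population-2 frequency gradient (~1% of
  SD) is inherent to sorting by F_ST within 125 marginal-quantile bins,
  as quantified above.
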