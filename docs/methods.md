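# Methods

This note documents the models implemented in `devpgs`, the synthetic
study generator that exercises them, the numerical choices made where the
design was genuinely open, and the limits of what the desk-scale validation
shows.

## Synthetic study generator

The generator (`devpgs.synthdata`) produces every input of the analysis
with the statistical structure the downstream methods assume, plus a
`TruthRecord` holding the planted quantities so recovery can be tested
without re-simulation. Fixing the seed fixes every emitted file
byte-for-byte.

**Genotypes.** Two latent Gaussian haplotypes per individual follow a
first-order autoregressive process within LD blocks and are thresholded at
the Φ⁻¹(MAF) quantile; the dosage is the number of sub-threshold
haplotypes. Marginal allele frequency is exact, genotypes are in
Hardy–Weinberg equilibrium by construction, and within-block LD decays
geometrically with SNP distance. Defaults: blocks of 8 SNPs at 10 kb
spacing (array-like density), per-block AR parameter drawn uniformly on
[0, 0.995]. Real genomes mix near-independent stretches with
near-duplicate markers; this wide range reproduces that heterogeneity and
gives LD scores the spread that LD-score regression needs for slope and
intercept identification at desk-scale SNP counts. MAF is uniform on
[0.05, 0.5]; allele pairs are never strand-ambiguous.

**GWAS summary statistics.** Per-SNP true standardized effects follow the
planted factor model `b_d = √h²_d (Λ η + u_d)` with factor effects
`η ~ N(0, Φ/M)` and uniquenesses scaled so `Var(b_d) = h²_d/M`; the
cross-disorder covariance of true effects is the h²-scaled `ΛΦΛᵀ`.
Z-scores are generated analytically as `z = √N (R b) + R^{1/2} e` with `R`
the empirical within-block panel correlation: the LDSC expectation
`E[χ²_j] = 1 + N h² l_j/M` holds exactly, and the noise is LD-correlated
exactly as in a single-cohort GWAS — which is what makes the gene-level
null eigenvalue mixture correct. Defaults mirror the study conditions:
eight disorders, three correlated factors (neurodevelopmental, compulsive,
mood-psychotic; factor correlations 0.3–0.4), h² = 0.4, N = 50,000 per
disorder.

**Expression atlas.** Each donor contributes one sample per region (six
regions: CBC, AMY, MDTHAL, STR, HIP, NCX; 20 prenatal + 20 postnatal
donors). On the log2 scale a value is `μ_gene + donor intercept + timing
shift + noise` (donor sd 0.5, noise sd 1); planted prenatal genes sit
`expr_effect = 1.5` sample-level standard deviations above their postnatal
mean, postnatal genes the reverse; the fractions are 20% and 23% of genes
per region (the proportions the real atlas yields in the cerebellum),
drawn independently per region. Values are emitted as `2^y − 1`
(RPKM-like). Not emulated: age trajectories within a window, region–region
expression correlation, count noise — so passing tests show correct
inference under the stated two-group model, not robustness to those
features.

**Phenotypes.** Twelve scales (eleven CBCL-like, one child-psychosis-like)
are Cholesky-mixed to a target correlation matrix whose default is a
one-shared-factor structure giving CBCL pairwise correlations in 0.30–0.85
and psychosis correlations near 0.1 — the observed pattern in population
cohorts of this age. A configurable share (default 2%) of the Total
scale's variance is replaced by the true standardized genetic score of the
SNPs annotated to the causal partition (default: prenatally expressed
cerebellar genes, through the NDV factor effects). Site intercepts carry
2% of variance across 22 sites; age, sex and five ancestry PCs are stored
as covariates with no planted effect. Scales are reported as T-scores
(mean 50, sd 10) with the clinical flag at Total ≥ 64.

**Gene map.** The coordinate range is cut into `n_genes` equal slots with
one gene placed strictly inside each, so intervals are disjoint by
construction; strands are random. Coordinates are 1-based inclusive
internally and written 0-based half-open in BED-like files.

## QC chain

Order is fixed as variant filters → LD pruning → PCA outliers → IBD,
matching conventional PLINK workflows. The Hardy–Weinberg test is the
exact conditional test (weights `n!/(nAA! nAa! naa!)·2^nAa`), two-sided by
summing configurations no more probable than the observed one. QC removals
are attributed to the first failing criterion in the stated order, so
counts sum without double counting. Pruning scans left to right and drops
the later SNP of an offending pair; correlations use pairwise-complete
dosages. π̂ uses the method-of-moments IBS→IBD conversion with unbiased
falling-factorial moment estimators (as in PLINK); with few SNPs the
clipping of negative state estimates still biases π̂ upward, so relatedness
filtering should run on thousands of pruned markers.

## LD-score regression

LD scores sum adjusted r² (`r²_adj = r² − (1−r²)/(n−2)`) over a position
window, self term included. Each element of S comes from a two-step
weighted regression of `z_i z_j` on the LD score (first pass 1/l weights,
second pass adds the heteroskedasticity factor `1/(1 + N ĥ² l/M)²`), with
a free intercept; slopes convert to (co)variances by `M/√(N_i N_j)`.
`V = Cov(vech S)` is the delete-one jackknife over 200 contiguous SNP
blocks, computed from per-block sufficient statistics. Alleles are aligned
to the first trait (swap flips the beta sign; strand-ambiguous A/T and C/G
variants are dropped). If `V` is indefinite it is smoothed by eigenvalue
flooring at 1e-9 of the largest eigenvalue and flagged.

A precision note: at M = 20,000 regression SNPs the intercept has a
sampling sd of roughly 0.05–0.1 under any LD geometry — LD scores are
bounded below by 1, so the intercept is an extrapolation, and each LD
block contributes at most about one unit of slope information. Real
analyses obtain intercept standard errors near 0.01 only because M is two
orders of magnitude larger. Desk-scale validation therefore checks the
intercept tightly at the null (where no genetic variance propagates) and
the heritability under the planted signal.

## Genomic SEM

**EFA.** S is standardized to correlation scale, factored by minimum
residuals (uniquenesses optimized by L-BFGS-B, loadings from the leading
eigenpairs of the reduced matrix), varimax-rotated, then promax (power 4)
for an oblique pattern with factor correlations `Φ = (UᵀU)⁻¹`. Loadings
below 0.2 in absolute value are masked from factor definitions; the
proportion of genetic variance explained is the mean communality.

**CFA.** The correlated-factors model `Σ(θ) = ΛΦΛᵀ + Θ` (factor variances
fixed at 1) is fitted by diagonally-weighted least squares with weights
`1/diag(V)`. Standard errors use the sandwich with the full V. The model
χ² is Browne's residual-based statistic with the full (pseudo-inverted)
V, which is exactly zero for a saturated or perfectly fitting model; CFI
compares to the zero-covariance independence model, SRMR is the RMS
standardized residual, AIC = χ² + 2·(free parameters). Full-information
WLS (non-diagonal weight) is intentionally not the default: with a
jackknife V at desk scale its inverse is unstable.

**Common-factor GWAS.** Per-trait betas are standardized with the
reference allele frequency (`β_std = z/√(N·2p(1−p))`). Since the SNP is
exogenous, the model-implied SNP–indicator covariance is `Λ·cov(SNP, F)`,
so the SNP's factor effects solve a weighted least-squares projection of
its indicator covariances onto the loading matrix fixed at the base CFA
solution, with weights equal to the inverse per-trait sampling variances.
This reproduces the one-factor closed form (factor beta = b/λ), yields
exactly calibrated null p-values under independent per-trait GWAS noise,
and vectorizes over SNPs (full per-SNP refits would be thousands of times
slower for identical point estimates at small SNP effects, the regime
GWAS operates in). SNPs absent from any indicator are reported missing
and counted.

## Gene-based association

Windows are strand-aware: plus-strand genes take [start − 35 kb,
end + 10 kb], minus-strand genes the mirror image (a flag disables strand
awareness). The gene statistic is the mean χ² of the gene's SNPs; its null
is the eigenvalue mixture `Σ λ_i χ²₁` with eigenvalues of the SNPs'
dosage-correlation matrix (ridge 1e-6), approximated by a moment-matched
gamma (Satterthwaite). The approximation is exact for one SNP and for
independent SNPs; a Monte-Carlo option (1e5 draws) is provided for
validation, and the realized type-I error under an LD-aware global null is
within [0.04, 0.06] at α = 0.05. The tissue-property regression converts
gene p-values to probit z-scores and regresses them per tissue on that
tissue's log expression, covarying average expression, log gene length
and log SNP count, one-sided for positive slope with a Bonferroni
threshold 0.05/n_tissues.

## Developmental expression

The set-level mixed model uses crossed random intercepts for gene and
donor (REML); prenatal is coded 1, so positive β1 means higher prenatal
expression. If a variance component collapses it is dropped and the model
refit. Per-gene classification uses Welch t-tests on per-donor means
(replicates averaged first so donors are the independent unit — the mixed
model, not the t-test, is where within-donor correlation is modelled),
Benjamini–Hochberg across the genes of a region, sign of the
prenatal-minus-postnatal estimate for the class. Expression is
log2(x+1)-transformed by default (flag to disable); classification is
invariant to positive rescaling of the input.

## Polygenic scores

Clumping sorts by p (ties: position, then id) and accepts a SNP if its r²
with every previously accepted SNP within 250 kb is at most 0.1 (the
window is configurable; 250 kb is the conventional default). Scores sum
`β · dosage` over SNPs passing the Pt threshold, with missing dosages
imputed as twice the allele frequency and swapped alleles scored as
`2 − dosage`. Standardization is per column; quintiles come from a stable
sort split into five near-equal groups, so ties resolve by input order.
Partitioned scores subset the factor summary statistics to SNPs annotated
to at least one gene of a (region, class) cell — a SNP may appear in
several partitions — then clump and score each subset independently at
Pt = 1.0, giving exactly 18 columns.

## Association models

Phenotype regressions are REML mixed models with a site random intercept
(fixed covariates: age, sex, five PCs); single-site data fall back to OLS
automatically. ΔR² is the marginal (fixed-effects) R² — fixed-effect
variance over total variance — of the full minus the covariate-only model;
the conditional version (including site variance) is reported alongside.
Inference is Wald. Quintile odds ratios restrict to the top and bottom
quintile and fit a logistic model of the clinical flag on the top-quintile
indicator plus covariates; without covariates this equals the 2×2
cross-product OR with Woolf confidence limits, and an all-zero cell falls
back to the Haldane–Anscombe 0.5 correction (flagged). An emergent-mode
argument excludes individuals flagged at baseline before modelling.
Benjamini–Hochberg q-values are computed by the step-up rule with an
optional declared comparison count m (e.g., 36 = 3 scores × 12 scales).

## Problem sizes used in validation

The bundled validation and the acceptance script run at desk scale, chosen
so the whole suite completes in minutes on one CPU: LDSC at M = 20,000
SNPs (reference panel n = 800); factor-GWAS calibration and recovery at
2,000 SNPs; gene-test calibration over 2,000 replicate genes; timing
classification at 1,000 genes × 20 donors per window; the end-to-end
partitioned-score contrast at n = 2,000 individuals, 5,000 SNPs, 500
genes over 20 seeds; full-null error control over 50 seeds of a
1,000-individual study.

## Known limitations

- S is estimated on the observed/z scale of the simulated inputs; no
  liability-scale conversion, stratified LDSC, or GC correction.
- The common-factor GWAS holds the measurement model fixed at the base
  CFA solution; per-SNP heterogeneity (Q-statistics) is not computed.
- The LDSC intercept at desk-scale M has an irreducible sampling sd near
  0.05 (see above); single-run intercepts should be read with that in
  mind.
- The generator's phenotype model is stationary and linear; no
  development over waves, item-level structure, or missingness.
- π̂ is upward-noisy with few markers; run IBD filtering after pruning on
  thousands of SNPs.
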