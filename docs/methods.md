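# Methods

`ptrskit` implements a summary-statistics risk-scoring framework for a
binary phenotype and a synthetic-cohort generator that reproduces the
statistical structure such an analysis assumes. This note records the
models, the defaults and why, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The risk-scoring framework

**Polygenic risk score (C+T).** Variants are greedily clumped against an
external reference panel: the smallest-P unclaimed variant becomes an
index and removes unclaimed variants within a window whose squared
correlation with it exceeds `r2_max` (defaults r² = 0.1, 250 kb — the
conventional defaults of clumping tools; both exposed). The PRS at cutoff
*t* is `PRS_i = Σ_{l: P_l ≤ t} β_l X_il` with dosages counted on the
effect allele and missing dosages mean-imputed per variant. The cutoff is
chosen on the training set by maximal covariate-adjusted AUC over a
geometric grid from 5×10⁻⁸ to 1 (200 points by default; a fine grid in the
spirit of high-resolution threshold searches). P-value ties in clumping
break by (position, id) so results are row-order invariant; AUC ties in
the search keep the smaller cutoff.

**Summary-statistics TWAS.** For a gene with eQTL weights `w_lg` the gene
z-score combines per-variant GWAS z-scores with reference LD:

    z_g = Σ_l w_lg (σ_l / σ_g) z_l,   σ_g² = wᵀ Σ w,
    β̂_g = Σ_l w_lg σ_l² β_l / σ_g²,

where σ_l and Σ are always the dosage SDs and covariance of the external
reference panel, never of the GWAS. Genes with σ_g² ≤ 10⁻⁸ (a pure
numerical guard) or with no model variant present in the GWAS are dropped
and counted. Model variants absent from the GWAS are dropped from the
gene's weight vector before σ_g² is computed; region-wide summary
imputation (below) can run first to reduce that loss.

**Polygenic transcriptome risk score.** Per tissue,
`PTRS_i = Σ_{g: P_g ≤ t} T_ig β̂_g` with `T_ig = Σ_l w_lg X_il` the
predicted (genetically regulated) expression. The cutoff grid is fixed at
the nine values {1, 0.1, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 1e-7}; the
per-tissue model is the maximal covariate-adjusted training AUC, ties
resolved toward the more stringent cutoff (fewer genes).

**Standardization and transport.** Every score is standardized to zero
mean and unit population SD (ddof = 0) computed on the *training* set;
the same (μ, σ) transport to the test set. Within-set standardization is
available but not the default, to avoid test-set leakage. Covariate
adjustment ("adjusted for age, sex, 10 PCs") uses the fitted-probability
convention — the ROC predictor is the linear predictor of logistic
case ~ score + covariates — with a residualization mode as an
alternative; test-set evaluation transports training-fitted coefficients.

**Gene-based test and tissue enrichment.** The gene statistic is the mean
χ² of the variant z-scores in the gene window (±10 kb default). Its null
under LD is the eigenvalue mixture `(1/k) Σ λ_i χ²₁` with λ_i the
eigenvalues of the window LD matrix; the P-value uses Satterthwaite moment
matching (exact for k = 1 and for identity LD). Tissue relevance is an
OLS of gene Z = Φ⁻¹(1−P) on a tissue's standardized expression plus the
cross-tissue average (both standardized first, which makes the test
invariant to affine rescaling of any column), one-sided for positive
coefficients, Bonferroni-corrected across tissues. This is a deliberately
transparent stand-in for gene-property tools: technical covariates such as
gene length or variant density are omitted.

**Summary-statistic imputation.** Unobserved variant z-scores in a region
are imputed by the Gaussian conditional mean
`z_u = Σ_uo (Σ_oo + λI)⁻¹ z_o` with reference LD and ridge λ = 0.1
(configurable); the attached quality is `diag(Σ_uo (Σ_oo+λI)⁻¹ Σ_ou)`.
Effect sizes are back-filled from z via the frequency relation
`se = 1/√(2f(1−f)n)` at the median observed sample size.

**Baseline clinical model and combination.** The baseline is logistic
case ~ INT(eosinophils) + INT(lymphocytes) + age + sex, where INT is the
Blom rank-based inverse-normal transform, Φ⁻¹((r−3/8)/(n+1/4)), ties
averaged. Missing blood counts (missing completely at random in the
generator) are completed by single-imputation chained equations: each
incomplete count is iteratively regressed on age, sex, case status and the
other count with gradient-boosted regression trees (5 cycles; a linear
learner is the fallback). Single imputation rather than multiple: nothing
downstream pools across imputations. The combined score is the weighted
sum `ŵ_prs·PRS + ŵ_ptrs·PTRS` with weights from logistic
case ~ PRS + PTRS + covariates on the training set; covariates inform the
weights but do not enter the sum (they re-enter at evaluation). Tissues
whose PRS×PTRS interaction is Bonferroni-significant on the training set
are excluded from combination.

**Evaluation.** The c-statistic is the Mann–Whitney concordance (ties
count ½), which equals the trapezoidal area under the empirical ROC curve
identically; CIs use DeLong's structural-components variance (midrank
construction) by default, with a stratified bootstrap (10,000 resamples by
default) as an alternative, and paired curve comparisons use the full
DeLong covariance. The train/test split is stratified on case status, sex
and age quintile (the binning is a package choice) at an 80/20 ratio.

## The synthetic-data generator

The generator emulates: an external LD reference panel (633 individuals by
default), a target cohort (50,000 by default) with ~4% case prevalence, an
external base GWAS of 527,948 individuals summarized analytically, seven
candidate tissues with sparse (1–5 eQTL) prediction models of which a
configurable subset is causal, and blood counts correlated with liability
(+0.25 eosinophils, −0.12 lymphocytes) with 3% MCAR missingness. Those
defaults are the desk-scale rendering of the study design the framework
targets; the blood-count correlations are chosen to give clearly signed,
highly significant logistic associations at n = 50k, of the same order as
published eosinophil/lymphocyte log-odds in atopic disease.

**Genotypes.** Per LD block, a latent AR(1) normal vector is pushed
through the binomial(2, f) quantile (Hardy–Weinberg dosages {0,1,2}).
Discretization attenuates correlation, so the latent parameter of each
adjacent pair is calibrated — via bivariate-normal orthant probabilities
and root finding — to make the realized *dosage* correlation equal
`ld_rho`; MAFs are drawn around a block-level frequency with jitter that
shrinks as LD grows, since tightly linked variants necessarily have
similar frequencies. Two consequences worth knowing: longer-range LD
decays more slowly than ρ^distance (only the adjacent lag is calibrated),
and the calibration caches solutions on a 0.02 MAF grid for speed.

**Liability and phenotype.** Liability = mediated + direct + noise, where
the mediated component is Σ_g α_g T_g over causal genes and the direct
component Σ_l γ_l X_l over causal variants hosted on LD blocks disjoint
from all eQTL blocks. Disjointness makes the variance decomposition
additive and is the generative analog of PRS and PTRS carrying partly
independent information. Both components are empirically rescaled on the
realized cohort so the h² decomposition is exact by construction. Cases
are individuals above the Φ⁻¹(1−prevalence) liability quantile. Optional
product terms (mediated × lymphocyte latent, mediated × direct) plant
detectable interactions for power experiments. Blood-count latents anchor
on the pre-interaction liability, so `blood_count_effects` are
liability–count correlations; counts are mapped to a lognormal scale with
typical 10⁹ cells/L magnitudes.

**Base GWAS.** Rather than simulating half a million individuals,
z-scores are drawn block-wise from N(√n·R·b_std, R) with R the cohort
dosage correlation and b_std the standardized joint effects; β and se are
back-computed via β = z/√(2f(1−f)n). Case/control effects are treated on
the configured (log-odds-like) scale directly; no liability-scale
conversion is applied, as the pipeline consumes effects as given.

**What the generator does not emulate.** Real LD maps and their
heterogeneity, imputation quality, strand ambiguity in the wild (the
generator emits only unambiguous alleles; the harmonizer still handles
A/T–C/G), population substructure (PCs are the top singular vectors of the
dosage matrix, not ancestry axes), related individuals, the X chromosome,
control-exclusion questionnaires, and non-European ancestry. Passing
tests therefore demonstrate internal statistical correctness of the
methods under the assumed structure, not real-data performance.

## Validation experiments and problem sizes

`ptrskit.validation` re-runs each experiment from scratch under one seed:
ROC anchors (10 null replicates at n = 50,000 plus a perfectly separating
score); equivalence with independent oracles (greedy clumping vs an
exhaustive re-scan on 200 random instances of ≤30 variants; PRS/PTRS sums
vs per-individual loops; logistic fits vs textbook IRLS at 10⁻⁶;
concordance vs trapezoidal ROC at 10⁻¹²); summary-vs-individual TWAS
agreement on a 2,000-person cohort with a quantitative outcome where the
LD reference *is* the GWAS cohort (|Δz| < 0.05 for ≥95% of genes — the
remaining genes reflect the t ≈ r√n approximation at larger effects);
type-I error of the gene test over 10,000 null genes; DeLong CI coverage
over 500 simulations at n = 2,000 and true AUC 0.65; KS uniformity of
null TWAS and null interaction P-values across 5 seeds each; and a
20-seed parameter-recovery study at n = 50,000 with h²_mediated =
h²_direct = 0.2, prevalence 4%, one causal and one null tissue (disjoint
gene sets), a planted PTRS×lymphocyte liability interaction of 0.15, and
an 80/20 stratified split. The recovery study checks that the selected
PRS and causal-tissue PTRS separate cases from controls (DeLong P < 0.01
versus 0.5), that the combined score's training log-likelihood dominates
its nested single-score models, that the causal tissue outranks the null
tissue, and that the planted interaction is detected at the
Bonferroni-corrected level. Problem sizes (400 variants over 16 blocks,
25 genes per tissue, a 50-point threshold grid in the multi-seed loops)
keep each experiment at desk scale while leaving every statistical claim
at its stated strength.

Null-uniformity experiments use `ld_rho = 0` or block-independent genes:
marginal uniformity is the calibration claim, and KS requires exchangeable
draws, which within-block LD would violate even for a perfectly calibrated
generator.

## Numerical choices and degenerate inputs

P-values of 0/1 are clamped into the open interval (downstream quantile
math); σ_g² guard 10⁻⁸; near-singular LD blocks get a ridge before the
Cholesky draw; strand-ambiguous variants are dropped by default, or
oriented by frequency (|eaf−0.5| > 0.1) on request; monomorphic variants
are excluded from LD with a report; constant scores raise a degenerate-
score error rather than dividing by zero; separation in logistic fits
falls back to a small-ridge fit with penalized-Hessian standard errors and
a warning; empty threshold sets yield zero scores with n_features = 0 and
a warning.

## Known limitations

The gene-based test is a simplified mean-χ² model, not a full
multi-model gene association tool; the PTRS is the summary-statistics
formulation (no individual-level elastic-net training); combination uses
a single weighted sum, not stacking or cross-validated averaging; the
c-statistic machinery covers discrimination only (no calibration or
reclassification metrics); and all fidelity claims are relative to the
generator's idealized LD and effect structure.
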