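# ptrskit

Polygenic and transcriptome risk scores for binary disease phenotypes.

`ptrskit` is for statistical geneticists who want to build and compare,
under one roof: a clumping-and-thresholding polygenic risk score (PRS)
from GWAS summary statistics, tissue-specific polygenic *transcriptome*
risk scores (PTRS) built from summary-level TWAS gene effects and
predicted expression, a clinical baseline model from blood-cell counts,
and weighted combinations of all of the above — evaluated with
covariate-adjusted ROC c-statistics and DeLong comparisons. Because the
individual-level biobank data such analyses run on is access-restricted,
the package ships a first-class synthetic-cohort generator that
reproduces the statistical structure the analysis assumes (LD-structured
genotypes, sparse cis-eQTL weight models, a liability-threshold phenotype
with expression-mediated and direct variant effects, an analytically
summarized external base GWAS, and blood counts tied to liability with
opposite signs), plus a ground-truth record for parameter-recovery
experiments.

## The models

**C+T PRS.** Greedy clumping against an external LD reference (index =
smallest-P unclaimed variant; remove unclaimed variants with r² above
threshold within a window), then

    PRS_i = Σ_{l : P_l ≤ t} β_l X_il

with the cutoff *t* chosen by maximal covariate-adjusted AUC on the
training set over a geometric grid.

**Summary-statistics TWAS and PTRS.** Per tissue, gene effects come from
the summary-level estimator

    z_g = Σ_l w_lg (σ_l/σ_g) z_l ,   σ_g² = wᵀΣw ,
    β̂_g = Σ_l w_lg σ_l² β_l / σ_g² ,

with eQTL weights w_lg and reference-panel LD Σ, and the score is

    PTRS_i = Σ_{g : P_g ≤ t} T_ig β̂_g ,  T_ig = Σ_l w_lg X_il

over the fixed gene-P grid {1, 0.1, 5e-2, …, 1e-7}. Scores are
standardized on the training set (the same μ, σ transport to test) and
adjusted for age, sex and 10 genetic PCs. The combined score is
ŵ_prs·PRS + ŵ_ptrs·PTRS with weights from a training logistic fit,
after screening out tissues with a significant PRS×PTRS interaction.
Discrimination is Harrell's c with DeLong (or stratified-bootstrap) CIs
and paired DeLong Δc tests. See `docs/methods.md` for assumptions,
defaults and numerical details.

## Worked example

```python
from ptrskit import SimulationConfig, run_pipeline

cfg = SimulationConfig(n_cohort=10_000, n_ref=633, n_blocks=8, block_size=20,
                       n_tissues=2, genes_per_tissue=15, n_causal_tissues=1,
                       shared_gene_fraction=0.0, h2_mediated=0.08,
                       h2_direct=0.08, seed=7)
res = run_pipeline(cfg, grid_size=50)
print("best PRS threshold:", f"{res['prs_model'].best_threshold_:.3g}",
      "| variants:", res['prs_model'].n_features_)
print(res["suite"].models[["model", "c", "ci_low", "ci_high"]].round(3))
```

prints (exactly, for this seed):

```
best PRS threshold: 5e-08 | variants: 21
                          model     c  ci_low  ci_high
                            prs 0.734   0.683    0.786
                  ptrs_tissue_0 0.724   0.671    0.776
                  ptrs_tissue_1 0.717   0.665    0.769
              combined_tissue_0 0.736   0.684    0.789
              combined_tissue_1 0.730   0.677    0.782
                       baseline 0.716   0.659    0.773
              baseline_plus_prs 0.738   0.686    0.791
baseline_plus_combined_tissue_0 0.740   0.687    0.793
baseline_plus_combined_tissue_1 0.735   0.682    0.788
```

Reading it: the clumped PRS at its selected cutoff includes 21 variants
and separates cases from controls with test-set c = 0.734; the causal
tissue's PTRS (tissue_0) outperforms the null tissue's (0.724 vs 0.717,
the latter nonzero only through LD leakage into its eQTLs); combining
PRS with PTRS and then with the clinical baseline nudges the c-statistic
up to 0.740, the familiar pattern of PRS dominating single-tissue PTRS
while combinations help at the margin. `res["suite"].comparisons` holds
the paired DeLong Δc tests for these curves.

The same chain is scriptable from a shell: `ptrskit simulate`,
`harmonize`, `impute-z`, `clump`, `enrich`, `twas`, `prs`, `ptrs`,
`baseline`, `combine`, `interactions`, `split`, `evaluate`, or everything
at once with `ptrskit pipeline config.yaml outdir/`.

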