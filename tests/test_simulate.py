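"""Generator fidelity: LD structure, liability decomposition, prevalence,
blood-count directions and analytic summary-statistic calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptrskit.datatypes import ConfigurationError
from ptrskit.simulate import (
    SimulationConfig,
    joint_standardized_effects,
    simulate_cohort,
    simulate_eqtl_models,
    simulate_gwas_sumstats,
    simulate_reference_panel,
    simulate_study,
)
from ptrskit.datatypes import GroundTruth


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(h2_mediated=0.6, h2_direct=0.5)
    with pytest.raises(ConfigurationError):
        SimulationConfig(prevalence=0.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(ld_rho=1.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(eqtl_per_gene=(3, 20), block_size=10)


def test_same_seed_bit_identical():
    cfg = SimulationConfig(n_ref=100, n_cohort=300, n_blocks=3, block_size=5,
                           n_tissues=2, genes_per_tissue=4, seed=11)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    np.testing.assert_array_equal(a["reference_panel"].dosages,
                                  b["reference_panel"].dosages)
    np.testing.assert_array_equal(a["cohort_panel"].dosages,
                                  b["cohort_panel"].dosages)
    pd.testing.assert_frame_equal(a["sumstats"], b["sumstats"])
    pd.testing.assert_frame_equal(a["cohort"], b["cohort"])


def test_no_ld_gives_uncorrelated_genotypes():
    cfg = SimulationConfig(n_ref=1000, n_blocks=2, block_size=10, ld_rho=0.0,
                           seed=3)
    panel = simulate_reference_panel(cfg)
    R = np.corrcoef(panel.dosages[:, :10].T)
    off = np.abs(R[np.triu_indices(10, 1)])
    assert off.mean() < 0.05


def test_high_ld_adjacent_correlation_matches_target():
    # dosage-scale adjacent correlation should track ld_rho=0.9
    vals = []
    for seed in range(6):
        cfg = SimulationConfig(n_ref=2000, n_blocks=2, block_size=10,
                               ld_rho=0.9, seed=seed)
        panel = simulate_reference_panel(cfg)
        for b in range(2):
            R = np.corrcoef(panel.dosages[:, b * 10:(b + 1) * 10].T)
            vals.append(np.mean(np.diag(R, 1)))
    assert 0.8 <= np.mean(vals) <= 0.95


def test_maf_within_bounds():
    cfg = SimulationConfig(n_ref=2000, n_blocks=4, block_size=10,
                           maf_range=(0.1, 0.4), seed=5)
    panel = simulate_reference_panel(cfg)
    f = panel.dosages.mean(axis=0) / 2
    maf = np.minimum(f, 1 - f)
    assert (maf > 0.05).all() and (maf < 0.45).all()


def test_eqtl_model_shapes_and_sharing():
    cfg = SimulationConfig(n_ref=200, n_blocks=4, block_size=8, n_tissues=3,
                           genes_per_tissue=6, eqtl_per_gene=(1, 1), seed=2)
    panel = simulate_reference_panel(cfg)
    models, _ = simulate_eqtl_models(cfg, panel)
    for m in models:
        assert all(len(m.gene_entries(g)) == 1 for g in m.genes)
    cfg_shared = SimulationConfig(n_ref=200, n_blocks=4, block_size=8,
                                  n_tissues=3, genes_per_tissue=6,
                                  shared_gene_fraction=1.0, seed=2)
    models, _ = simulate_eqtl_models(cfg_shared, panel)
    gene_sets = [set(m.genes) for m in models]
    assert gene_sets[0] == gene_sets[1] == gene_sets[2]


def test_grex_variance_matches_quadratic_form():
    # w' Sigma w from the panel should match the Monte-Carlo variance of
    # predicted expression over freshly simulated individuals
    cfg = SimulationConfig(n_ref=2000, n_cohort=5000, n_blocks=2,
                           block_size=10, n_tissues=1, genes_per_tissue=5,
                           eqtl_per_gene=(5, 5), ld_rho=0.5, seed=9)
    panel = simulate_reference_panel(cfg)
    models, truth = simulate_eqtl_models(cfg, panel)
    cohort_panel, _, _ = simulate_cohort(cfg, models, truth, panel)
    vindex = panel.variant_index()
    X_ref = panel.dosages
    for g in models[0].genes:
        sub = models[0].gene_entries(g)
        idx = vindex.get_indexer(sub["variant_id"])
        w = sub["weight"].to_numpy(float)
        Sigma = np.cov(X_ref[:, idx].T)
        qform = float(w @ Sigma @ w)
        t = cohort_panel.dosages[:, idx] @ w
        assert abs(t.var() - qform) / qform < 0.15


def test_prevalence_and_missingness():
    cfg = SimulationConfig(n_cohort=20_000, n_ref=300, n_blocks=6,
                           block_size=10, n_tissues=1, genes_per_tissue=5,
                           prevalence=0.04, missing_rate=0.03, seed=4)
    study = simulate_study(cfg)
    cohort = study["cohort"]
    assert 0.035 <= cohort["case"].mean() <= 0.045
    assert 0.025 <= cohort["eosinophils"].isna().mean() <= 0.035


def test_heritability_decomposition_exact():
    cfg = SimulationConfig(n_cohort=20_000, n_ref=300, n_blocks=6,
                           block_size=10, n_tissues=2, genes_per_tissue=8,
                           h2_mediated=0.25, h2_direct=0.15, seed=8)
    study = simulate_study(cfg)
    comp = study["truth"].components
    assert abs(comp["mediated"].var() - 0.25) < 0.025
    assert abs(comp["direct"].var() - 0.15) < 0.015
    assert abs(study["truth"].liability.var() - 1.0) < 0.1


def test_blood_count_directions():
    from ptrskit.models import rank_inverse_normal
    import statsmodels.api as sm

    cfg = SimulationConfig(n_cohort=20_000, n_ref=300, n_blocks=6,
                           block_size=10, n_tissues=1, genes_per_tissue=5,
                           missing_rate=0.0, seed=6)
    study = simulate_study(cfg)
    cohort = study["cohort"]
    y = cohort["case"].to_numpy()
    for col, sign in (("eosinophils", 1), ("lymphocytes", -1)):
        x = rank_inverse_normal(cohort[col])
        res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        z = res.params[1] / res.bse[1]
        assert sign * z > 3


def test_null_sumstats_calibrated():
    cfg = SimulationConfig(n_ref=500, n_blocks=1000, block_size=10,
                           ld_rho=0.0, h2_mediated=0.0, h2_direct=0.0, seed=1)
    panel = simulate_reference_panel(cfg)
    stats_df = simulate_gwas_sumstats(cfg, GroundTruth(), panel)
    z = stats_df["z"].to_numpy()
    assert abs(z.mean()) < 0.03
    assert 0.95 <= z.var() <= 1.05
    ks = stats.kstest(stats_df["p"], "uniform")
    assert ks.pvalue > 0.01


def _single_causal_setup(ld_rho, seed):
    cfg = SimulationConfig(n_ref=3000, n_blocks=1, block_size=2,
                           eqtl_per_gene=(1, 2), ld_rho=ld_rho,
                           n_base_gwas=500_000, seed=seed)
    panel = simulate_reference_panel(cfg)
    sd = panel.dosages.std(axis=0)
    truth = GroundTruth(true_variant_effects={
        panel.variants.loc[0, "id"]: 0.02 / sd[0]})
    return cfg, panel, truth


def test_single_causal_noncentrality():
    # E[z] = b_std * sqrt(n) = 0.02 * sqrt(5e5) ~ 14.14
    cfg, panel, truth = _single_causal_setup(0.0, 21)
    zs = []
    for rep in range(200):
        s = simulate_gwas_sumstats(cfg, truth, panel,
                                   rng=np.random.default_rng(1000 + rep))
        zs.append(s["z"].iloc[0])
    assert 13.5 <= np.mean(zs) <= 14.8


def test_ld_leaks_noncentrality_to_null_neighbor():
    # a null variant at dosage correlation r inherits r times the causal
    # variant's expected z
    cfg, panel, truth = _single_causal_setup(0.9, 22)
    r = np.corrcoef(panel.dosages.T)[0, 1]
    z0, z1 = [], []
    for rep in range(200):
        s = simulate_gwas_sumstats(cfg, truth, panel,
                                   rng=np.random.default_rng(2000 + rep))
        z0.append(s["z"].iloc[0])
        z1.append(s["z"].iloc[1])
    ratio = np.mean(z1) / np.mean(z0)
    assert abs(ratio - r) < 0.05
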