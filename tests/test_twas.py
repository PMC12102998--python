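"""GReX prediction and summary-level gene association, including the
individual-level oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptrskit.datatypes import LdBlockMatrix, WeightModel
from ptrskit.ld import compute_ld, compute_ld_blocks
from ptrskit.simulate import (
    SimulationConfig,
    marginal_gwas,
    simulate_cohort,
    simulate_eqtl_models,
    simulate_gwas_sumstats,
    simulate_reference_panel,
)
from ptrskit.datatypes import GroundTruth
from ptrskit.twas import predict_grex, spredixcan
from conftest import make_panel


def _model(weights, eas=None, oas=None, gene="G1", ids=None):
    k = len(weights)
    return WeightModel("tissueA", pd.DataFrame({
        "gene": gene,
        "variant_id": ids or [f"v{i}" for i in range(k)],
        "ea": eas or ["A"] * k,
        "oa": oas or ["G"] * k,
        "weight": weights,
    }))


def test_grex_hand_dot_product():
    panel = make_panel(np.array([[2.0, 1.0], [0.0, 2.0]]))
    grex = predict_grex(panel, _model([0.5, -1.0]))
    assert grex.values[0, 0] == pytest.approx(0.5 * 2 - 1.0 * 1)
    assert grex.values[1, 0] == pytest.approx(0.5 * 0 - 1.0 * 2)


def test_grex_allele_flip_uses_two_minus_x():
    panel = make_panel(np.array([[0.5], [1.0]]))
    # model effect allele = panel ref -> contribution w*(2-X)
    grex = predict_grex(panel, _model([1.0], eas=["G"], oas=["A"]))
    assert grex.values[0, 0] == pytest.approx(1.5)


def test_grex_drops_unmatched_genes():
    panel = make_panel(np.array([[1.0], [0.0]]))
    model = WeightModel("t", pd.DataFrame({
        "gene": ["G1", "G2"], "variant_id": ["v0", "ghost"],
        "ea": ["A", "A"], "oa": ["G", "G"], "weight": [1.0, 2.0],
    }))
    grex = predict_grex(panel, model)
    assert grex.genes == ["G1"]
    assert grex.dropped_genes == ["G2"]


def _stats_from(z, beta=None, se=1.0):
    z = np.asarray(z, float)
    beta = z * se if beta is None else np.asarray(beta, float)
    df = pd.DataFrame({
        "chrom": "1", "pos": np.arange(100, 100 + len(z)),
        "id": [f"v{i}" for i in range(len(z))],
        "ea": "A", "oa": "G", "eaf": 0.3, "beta": beta,
        "se": beta / z if (z != 0).all() else se,
        "p": 2 * stats.norm.sf(np.abs(z)), "n": 1000.0, "z": z,
    })
    return df


def _ld(R, sd):
    m = len(sd)
    return LdBlockMatrix(np.array([f"v{i}" for i in range(m)]),
                         np.arange(100.0, 100 + m), np.asarray(R, float),
                         np.full(m, 0.3), np.asarray(sd, float))


def test_single_variant_collapse():
    for w in (0.7, -0.7):
        assoc = spredixcan(_stats_from([2.5]), _model([w]),
                           _ld(np.eye(1), [0.4]))
        assert assoc["zscore"].iloc[0] == pytest.approx(np.sign(w) * 2.5)


def test_two_variant_hand_value():
    # sigma_g^2 = 0.25 + 0.25 = 0.5; z_g = (0.5*2 + 0.5*2)/sqrt(0.5)
    assoc = spredixcan(_stats_from([2.0, 2.0]), _model([1.0, 1.0]),
                       _ld(np.eye(2), [0.5, 0.5]))
    assert assoc["pred_var"].iloc[0] == pytest.approx(0.5)
    assert assoc["zscore"].iloc[0] == pytest.approx(2.0 / np.sqrt(0.5))


def test_scale_and_sign_equivariance():
    sdf = _stats_from([1.2, -0.4, 2.2])
    ld = _ld(0.5 ** np.abs(np.subtract.outer(range(3), range(3))),
             [0.5, 0.6, 0.7])
    base = spredixcan(sdf, _model([0.3, -0.2, 0.9]), ld)
    scaled = spredixcan(sdf, _model([0.9, -0.6, 2.7]), ld)
    assert scaled["zscore"].iloc[0] == pytest.approx(base["zscore"].iloc[0])
    assert scaled["effect"].iloc[0] == pytest.approx(base["effect"].iloc[0] / 3)
    neg = spredixcan(sdf, _model([-0.3, 0.2, -0.9]), ld)
    assert neg["zscore"].iloc[0] == pytest.approx(-base["zscore"].iloc[0])
    assert neg["effect"].iloc[0] == pytest.approx(-base["effect"].iloc[0])


def test_gene_without_gwas_variants_skipped():
    sdf = _stats_from([1.0])
    model = WeightModel("t", pd.DataFrame({
        "gene": ["G2"], "variant_id": ["ghost"], "ea": ["A"], "oa": ["G"],
        "weight": [1.0]}))
    assoc = spredixcan(sdf, model, _ld(np.eye(1), [0.5]))
    assert len(assoc) == 0
    assert assoc.attrs["skipped_missing"] == 1


def test_summary_matches_individual_level_oracle():
    # with the LD reference equal to the GWAS cohort itself, the summary
    # gene z-score reproduces the individual-level GReX regression z
    # moderate polygenic signal: the summary estimator's t ~ r*sqrt(n)
    # approximation holds per variant, so summary and individual z agree
    cfg = SimulationConfig(n_ref=2000, n_cohort=2000, n_blocks=10,
                           block_size=10, n_tissues=1, genes_per_tissue=50,
                           ld_rho=0.6, h2_mediated=0.1, h2_direct=0.0,
                           seed=31)
    panel = simulate_reference_panel(cfg)
    models, truth = simulate_eqtl_models(cfg, panel)
    cpanel, cohort, truth = simulate_cohort(cfg, models, truth, panel)
    y = truth.liability
    gwas = marginal_gwas(cpanel, y)
    ld = compute_ld_blocks(cpanel)
    assoc = spredixcan(gwas, models[0], ld).set_index("gene")
    grex = predict_grex(cpanel, models[0])
    diffs = []
    for g in grex.genes:
        t = grex.gene_values(g)
        if t.std() == 0:
            continue
        r = np.corrcoef(t, y)[0, 1]
        z_ind = r * np.sqrt((len(y) - 2) / (1 - r ** 2))
        diffs.append(abs(assoc.loc[g, "zscore"] - z_ind))
    frac = np.mean(np.array(diffs) < 0.05)
    assert frac >= 0.95


def test_null_gene_pvalues_uniform():
    cfg = SimulationConfig(n_ref=400, n_blocks=400, block_size=4,
                           eqtl_per_gene=(1, 3), n_tissues=1,
                           genes_per_tissue=1000, ld_rho=0.4,
                           h2_mediated=0.0, h2_direct=0.0, seed=17)
    panel = simulate_reference_panel(cfg)
    models, truth = simulate_eqtl_models(cfg, panel)
    sdf = simulate_gwas_sumstats(cfg, GroundTruth(), panel)
    ld = compute_ld_blocks(panel)
    assoc = spredixcan(sdf, models[0], ld)
    ks = stats.kstest(assoc["pvalue"], "uniform")
    assert ks.pvalue > 0.01
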