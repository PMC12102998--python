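"""Validation experiments: analytic anchors, independent-oracle
equivalence, statistical calibration and parameter recovery on synthetic
cohorts.

Each function re-runs the relevant part of the pipeline from scratch under
a caller-supplied seed and returns plain numbers, so the same experiments
back both the test suite and the reproducibility script. The oracles here
are deliberately naive re-implementations (exhaustive re-scan clumping,
per-individual scoring loops, textbook IRLS, trapezoidal ROC integration)
kept independent of the production code paths they check.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GroundTruth
from .enrichment import GeneDefinition, gene_test
from .evaluate import adjusted_cstat, concordance, roc_auc_trapezoid
from .ld import clump, compute_ld_blocks
from .models import _logit_fit, impute_missing, risk_interaction
from .pipeline import pipeline_fingerprint, run_pipeline
from .prs import score_prs
from .ptrs import compute_ptrs
from .simulate import (
    SimulationConfig,
    marginal_gwas,
    simulate_cohort,
    simulate_eqtl_models,
    simulate_gwas_sumstats,
    simulate_reference_panel,
)
from .twas import GrexMatrix, predict_grex, spredixcan


# ---------------------------------------------------------------------------
# 1. analytic anchors

def cstat_anchors(seed: int, n: int = 50_000, prevalence: float = 0.04,
                  n_reps: int = 10) -> dict:
    """c-statistic of an outcome-independent score (replicated, with the
    rate at which the DeLong CI covers 0.5) and of a perfectly separating
    score."""
    rng = np.random.default_rng(seed)
    cs = []
    covered = 0
    for _ in range(n_reps):
        y = (rng.random(n) < prevalence).astype(int)
        cs_null = adjusted_cstat(rng.standard_normal(n), covariates=None, y=y)
        cs.append(cs_null.estimate)
        covered += cs_null.ci_low <= 0.5 <= cs_null.ci_high
    y = (rng.random(n) < prevalence).astype(int)
    perfect = y + rng.uniform(-0.4, 0.4, n)
    cs_perfect = adjusted_cstat(perfect, covariates=None, y=y)
    return {
        "cstat_random_score": float(np.mean(cs)),
        "cstat_random_covers_half": covered / n_reps,
        "cstat_perfect_score": cs_perfect.estimate,
        "n": n,
    }


# ---------------------------------------------------------------------------
# 2. independent-oracle equivalence

def _brute_force_clump(stats_df, panel, r2_max, window_kb):
    df = stats_df.sort_values(["p", "pos", "id"], kind="mergesort")
    alive = list(df.index)
    pidx = panel.variant_index()
    X = panel.dosages
    retained = []
    while alive:
        i = alive.pop(0)
        retained.append(df.loc[i, "id"])
        survivors = []
        for j in alive:
            close = (df.loc[i, "chrom"] == df.loc[j, "chrom"]
                     and abs(df.loc[i, "pos"] - df.loc[j, "pos"])
                     <= window_kb * 1000)
            if close:
                ii = pidx.get_indexer([df.loc[i, "id"]])[0]
                jj = pidx.get_indexer([df.loc[j, "id"]])[0]
                if ii >= 0 and jj >= 0:
                    r = np.corrcoef(X[:, ii], X[:, jj])[0, 1]
                    if np.isfinite(r) and r * r > r2_max:
                        continue
            survivors.append(j)
        alive = survivors
    return retained


def _random_panel_stats(rng, m, n=40):
    from .datatypes import GenotypePanel

    rho = rng.uniform(0, 0.95)
    R = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    L = np.linalg.cholesky(R)
    dosages = np.clip(1.0 + (rng.standard_normal((n, m)) @ L.T) * 0.4, 0, 2)
    spacing = int(rng.choice([1000, 150_000]))
    variants = pd.DataFrame({
        "chrom": "1", "pos": [1 + j * spacing for j in range(m)],
        "id": [f"v{j}" for j in range(m)], "ref": "G", "alt": "A",
        "block": 0,
    })
    panel = GenotypePanel(np.array([f"s{i}" for i in range(n)]), variants,
                          dosages)
    sdf = pd.DataFrame({
        "chrom": "1", "pos": variants["pos"], "id": variants["id"],
        "ea": "A", "oa": "G", "eaf": 0.3,
        "beta": rng.normal(0, 0.2, m), "se": 0.05,
        "p": rng.uniform(1e-8, 1, m), "n": 1000.0,
    })
    sdf["z"] = sdf["beta"] / sdf["se"]
    return panel, sdf


def oracle_checks(seed: int, n_clump_instances: int = 200) -> dict:
    rng = np.random.default_rng(seed)
    # clumping vs exhaustive re-scan
    agree = 0
    for _ in range(n_clump_instances):
        m = int(rng.integers(2, 31))
        panel, sdf = _random_panel_stats(rng, m)
        r2_max = float(rng.choice([0.05, 0.1, 0.3]))
        mine = list(clump(sdf, panel, r2_max=r2_max, window_kb=250)["id"])
        agree += mine == _brute_force_clump(sdf, panel, r2_max, 250)
    # PRS / PTRS sums vs per-individual loops
    prs_diff = 0.0
    ptrs_diff = 0.0
    for _ in range(10):
        m = int(rng.integers(1, 51))
        panel, sdf = _random_panel_stats(rng, m, n=int(rng.integers(5, 101)))
        t = float(rng.uniform(0, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = score_prs(panel, sdf, sdf, t)
        expected = np.zeros(panel.n_samples)
        for _, row in sdf[sdf["p"] <= t].iterrows():
            j = list(panel.variants["id"]).index(row["id"])
            for i in range(panel.n_samples):
                expected[i] += row["beta"] * panel.dosages[i, j]
        prs_diff = max(prs_diff, float(np.abs(sc.raw - expected).max()))

        n_i, g = int(rng.integers(5, 101)), int(rng.integers(1, 51))
        grex = GrexMatrix(np.array([f"s{i}" for i in range(n_i)]),
                          [f"g{j}" for j in range(g)],
                          rng.standard_normal((n_i, g)), "t")
        assoc = pd.DataFrame({
            "gene": grex.genes, "tissue": "t", "zscore": 1.0,
            "effect": rng.standard_normal(g),
            "pvalue": rng.uniform(0, 1, g), "n_snps_used": 1,
            "pred_var": 1.0,
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            psc = compute_ptrs(grex, assoc, 0.5)
        expected = np.zeros(n_i)
        for j in range(g):
            if assoc["pvalue"][j] <= 0.5:
                for i in range(n_i):
                    expected[i] += grex.values[i, j] * assoc["effect"][j]
        ptrs_diff = max(ptrs_diff, float(np.abs(psc.raw - expected).max()))
    # logistic fits vs textbook IRLS
    irls_diff = 0.0
    for _ in range(5):
        n_i = 500
        X = rng.standard_normal((n_i, 3))
        eta = -1.0 + X @ np.array([0.5, -0.3, 0.2])
        y = (rng.random(n_i) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = _logit_fit(y, pd.DataFrame(X, columns=list("abc")))
        beta = np.zeros(4)
        Xc = np.column_stack([np.ones(n_i), X])
        for _ in range(60):
            mu = 1 / (1 + np.exp(-(Xc @ beta)))
            W = mu * (1 - mu)
            zv = Xc @ beta + (y - mu) / W
            beta = np.linalg.solve((Xc * W[:, None]).T @ Xc,
                                   (Xc * W[:, None]).T @ zv)
        irls_diff = max(irls_diff,
                        float(np.abs(fit["estimate"].to_numpy() - beta).max()))
    # concordance vs trapezoidal ROC area
    trap_diff = 0.0
    for _ in range(20):
        n_i = int(rng.integers(20, 300))
        y = rng.integers(0, 2, n_i)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.standard_normal(n_i), 1)
        trap_diff = max(trap_diff,
                        abs(concordance(s, y) - roc_auc_trapezoid(s, y)))
    return {
        "clump_oracle_agreement": agree / n_clump_instances,
        "prs_loop_max_abs_diff": prs_diff,
        "ptrs_loop_max_abs_diff": ptrs_diff,
        "logit_irls_max_abs_diff": irls_diff,
        "cstat_trapezoid_max_abs_diff": trap_diff,
        "n": n_clump_instances,
    }


# ---------------------------------------------------------------------------
# 3. summary vs individual-level TWAS

def twas_equivalence(seed: int, n: int = 2000) -> dict:
    cfg = SimulationConfig(n_ref=n, n_cohort=n, n_blocks=10, block_size=10,
                           n_tissues=1, genes_per_tissue=50, ld_rho=0.6,
                           h2_mediated=0.1, h2_direct=0.0, seed=seed)
    panel = simulate_reference_panel(cfg)
    models, truth = simulate_eqtl_models(cfg, panel)
    cpanel, _, truth = simulate_cohort(cfg, models, truth, panel)
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
    return {
        "twas_summary_individual_agreement": float(
            np.mean(np.asarray(diffs) < 0.05)),
        "n": len(diffs),
    }


# ---------------------------------------------------------------------------
# 4. statistical calibration

def gene_test_calibration(seed: int, n_genes: int = 10_000, k: int = 5) -> dict:
    from .datatypes import LdBlockMatrix

    rng = np.random.default_rng(seed)
    ld = LdBlockMatrix(np.array([f"v{i}" for i in range(k)]),
                       np.arange(100.0, 100 + k), np.eye(k),
                       np.full(k, 0.3), np.full(k, 0.65))
    gene = GeneDefinition("G", "1", 50, 5000, window_kb=1)
    rejections = 0
    base = pd.DataFrame({
        "chrom": "1", "pos": np.arange(100, 100 + k),
        "id": [f"v{i}" for i in range(k)], "ea": "A", "oa": "G",
        "eaf": 0.3, "se": 1.0, "n": 1000.0,
    })
    for _ in range(n_genes):
        z = rng.standard_normal(k)
        sdf = base.assign(beta=z, z=z, p=2 * stats.norm.sf(np.abs(z)))
        _, p = gene_test(sdf, ld, gene)
        rejections += p < 0.05
    return {"gene_test_type1_error": rejections / n_genes, "n": n_genes}


def delong_coverage(seed: int, n_sims: int = 500, n: int = 2000,
                    auc: float = 0.65, case_frac: float = 0.2) -> dict:
    rng = np.random.default_rng(seed)
    delta = np.sqrt(2) * stats.norm.ppf(auc)
    m = int(case_frac * n)
    covered = 0
    for _ in range(n_sims):
        y = np.r_[np.ones(m), np.zeros(n - m)].astype(int)
        score = np.r_[rng.normal(delta, 1, m), rng.normal(0, 1, n - m)]
        cs = adjusted_cstat(score, covariates=None, y=y)
        covered += cs.ci_low <= auc <= cs.ci_high
    return {"delong_ci_coverage": covered / n_sims, "n": n_sims}


def null_twas_ks(seed: int, n_genes: int = 1000, n_seeds: int = 5) -> dict:
    """Uniformity of null TWAS gene P-values: KS test per seed, pass rate
    at P > 0.01 across seeds."""
    pvals = []
    passed = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(n_ref=400, n_blocks=2 * n_genes, block_size=4,
                               eqtl_per_gene=(1, 3), n_tissues=1,
                               genes_per_tissue=n_genes, ld_rho=0.4,
                               h2_mediated=0.0, h2_direct=0.0, seed=seed + s)
        panel = simulate_reference_panel(cfg)
        models, _ = simulate_eqtl_models(cfg, panel)
        sdf = simulate_gwas_sumstats(cfg, GroundTruth(), panel)
        ld = compute_ld_blocks(panel)
        assoc = spredixcan(sdf, models[0], ld)
        p = float(stats.kstest(assoc["pvalue"], "uniform").pvalue)
        pvals.append(p)
        passed += p > 0.01
    return {"null_twas_ks_pass_rate": passed / n_seeds,
            "null_twas_ks_median_pvalue": float(np.median(pvals)),
            "n": n_seeds}


def null_interaction_ks(seed: int, n_seeds: int = 5, n_reps: int = 25,
                        n: int = 1500) -> dict:
    """Uniformity of null PTRS x lymphocyte interaction P-values: one KS
    test per seed over pooled replicates, pass rate at P > 0.01."""
    passed = 0
    kps = []
    for s in range(n_seeds):
        pvals = []
        for rep in range(n_reps):
            rng = np.random.default_rng(seed + 7000 + s * n_reps + rep)
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            eta = -2.2 + 0.5 * a + 0.4 * b
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            cohort = pd.DataFrame({
                "sample": [f"s{i}" for i in range(n)], "case": y,
                "age": rng.normal(55, 8, n), "sex": rng.integers(0, 2, n),
                "lymphocytes": rng.lognormal(0, 0.4, n),
            })
            from .datatypes import ScoreVector
            scores = {
                "t0": ScoreVector(cohort["sample"], a, standardized=a),
                "t1": ScoreVector(cohort["sample"], b, standardized=b),
            }
            out = risk_interaction(cohort, scores)
            pvals.extend(out["p"])
        p = float(stats.kstest(pvals, "uniform").pvalue)
        kps.append(p)
        passed += p > 0.01
    return {"null_interaction_ks_pass_rate": passed / n_seeds,
            "null_interaction_ks_median_pvalue": float(np.median(kps)),
            "n": n_seeds}


# ---------------------------------------------------------------------------
# 5. parameter recovery at study scale

def recovery_config(seed: int, n_cohort: int = 50_000) -> SimulationConfig:
    """The recovery-study conditions: two tissues (one causal, one null),
    equal mediated/direct heritability, 4% prevalence, 80/20 split, a
    planted PTRS x lymphocyte liability interaction."""
    return SimulationConfig(
        n_cohort=n_cohort, n_ref=633, n_blocks=16, block_size=25,
        ld_rho=0.7, n_tissues=2, genes_per_tissue=25, n_causal_tissues=1,
        shared_gene_fraction=0.0, h2_mediated=0.2, h2_direct=0.2,
        prevalence=0.04, train_fraction=0.8,
        lymph_ptrs_interaction=0.15, seed=seed,
    )


def parameter_recovery(seed: int, n_seeds: int = 20,
                       n_cohort: int = 50_000) -> dict:
    prs_sig = ptrs_sig = outrank = loglik_ok = detected = 0
    prs_cs, ptrs_cs = [], []
    for s in range(n_seeds):
        cfg = recovery_config(seed + 100 + s, n_cohort)
        res = run_pipeline(cfg, grid_size=50, include_baseline=False)
        cohort = res["cohort"]
        test = ~res["train_mask"]
        train = res["train_mask"]
        y = cohort["case"].to_numpy()

        def sig_above_half(values):
            cs = adjusted_cstat(values[test], covariates=None, y=y[test])
            se = (cs.ci_high - cs.estimate) / 1.959963984540054
            p = 2 * stats.norm.sf(abs(cs.estimate - 0.5) / max(se, 1e-12))
            return cs.estimate, (cs.estimate > 0.5 and p < 0.01)

        c_prs, ok = sig_above_half(res["prs"].values)
        prs_cs.append(c_prs)
        prs_sig += ok
        c_p0, ok0 = sig_above_half(res["ptrs_scores"]["tissue_0"].values)
        ptrs_cs.append(c_p0)
        ptrs_sig += ok0
        c_p1, _ = sig_above_half(res["ptrs_scores"]["tissue_1"].values)
        outrank += c_p0 > c_p1

        # nested-model train log-likelihood ordering
        cov_tr = cohort.loc[train, ["age", "sex"]
                            + [c for c in cohort.columns if c.startswith("pc")]]
        y_tr = y[train]

        def llf_of(*scores):
            X = cov_tr.copy()
            for i, v in enumerate(scores):
                X.insert(i, f"s{i}", v[train])
            return _logit_fit(y_tr, X).attrs["llf"]

        ll_both = llf_of(res["prs"].values,
                         res["ptrs_scores"]["tissue_0"].values)
        ll_prs = llf_of(res["prs"].values)
        ll_ptrs = llf_of(res["ptrs_scores"]["tissue_0"].values)
        loglik_ok += ll_both >= max(ll_prs, ll_ptrs) - 1e-6

        # planted PTRS x lymphocyte interaction
        completed, _ = impute_missing(cohort, seed=cfg.seed)
        inter = risk_interaction(completed, res["ptrs_scores"])
        p0 = inter.set_index("tissue").loc["tissue_0", "p"]
        detected += p0 < 0.05 / 2
    return {
        "prs_cstat_significant_rate": prs_sig / n_seeds,
        "ptrs_cstat_significant_rate": ptrs_sig / n_seeds,
        "causal_tissue_outrank_rate": outrank / n_seeds,
        "combined_loglik_dominates_rate": loglik_ok / n_seeds,
        "interaction_detection_rate": detected / n_seeds,
        "mean_prs_test_cstat": float(np.mean(prs_cs)),
        "mean_ptrs_test_cstat": float(np.mean(ptrs_cs)),
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# 6. determinism

def pipeline_determinism(seed: int) -> dict:
    cfg = SimulationConfig(n_ref=200, n_cohort=1500, n_blocks=6,
                           block_size=8, n_tissues=2, genes_per_tissue=6,
                           eqtl_per_gene=(1, 3), ld_rho=0.5, seed=seed)
    a = pipeline_fingerprint(run_pipeline(cfg, grid_size=15))
    b = pipeline_fingerprint(run_pipeline(cfg, grid_size=15))
    return {"pipeline_bit_reproducible": float(a == b), "n": 2}
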