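"""Inverse-normal transform, chained-equation imputation, baseline and
combined risk models, interaction analyses; regression fits are checked
against an independent IRLS/normal-equations oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptrskit.datatypes import PC_COLUMNS, ScoreVector
from ptrskit.models import (
    CollinearScoresError,
    biomarker_association,
    combine_scores,
    fit_baseline,
    impute_missing,
    interaction_screen,
    rank_inverse_normal,
    risk_interaction,
    _logit_fit,
)
from ptrskit.simulate import SimulationConfig, simulate_study


# --------------------------------------------------------------------------
# independent oracles

def irls_logistic(y, X, tol=1e-12, max_iter=100):
    """Plain IRLS on the augmented design (intercept first)."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xc.shape[1])
    for _ in range(max_iter):
        eta = Xc @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        new = np.linalg.solve((Xc * W[:, None]).T @ Xc, (Xc * W[:, None]).T @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    cov = np.linalg.inv((Xc * W[:, None]).T @ Xc)
    return beta, np.sqrt(np.diag(cov))


# --------------------------------------------------------------------------
# rank-based inverse normal transform

def test_int_hand_values():
    out = rank_inverse_normal([1.0, 2.0, 3.0])
    expected = stats.norm.ppf([0.625 / 3.25, 0.5, 2.625 / 3.25])
    np.testing.assert_allclose(out, expected, atol=1e-10)
    assert out[1] == 0.0


def test_int_ties_share_average_rank():
    out = rank_inverse_normal([5.0, 5.0, 9.0])
    assert out[0] == out[1]
    expected = stats.norm.ppf((1.5 - 3 / 8) / 3.25)
    assert out[0] == pytest.approx(expected)


def test_int_preserves_order_and_missing():
    x = np.array([3.0, np.nan, 1.0, 7.0])
    out = rank_inverse_normal(x)
    assert np.isnan(out[1])
    assert out[2] < out[0] < out[3]


def test_int_constant_warns_zero():
    with pytest.warns(UserWarning):
        out = rank_inverse_normal([2.0, 2.0, 2.0])
    assert np.all(out == 0)


def test_int_output_is_normal():
    rng = np.random.default_rng(0)
    x = rng.lognormal(0, 1, 2000)
    out = rank_inverse_normal(x)
    assert stats.kstest(out, "norm").pvalue > 0.01


# --------------------------------------------------------------------------
# chained-equation imputation

def _cohort_with_missing(rng, n=3000, miss=0.03):
    latent = rng.standard_normal(n)
    eos = np.exp(0.5 * latent + rng.normal(0, 0.5, n))
    lym = np.exp(-0.4 * latent + rng.normal(0, 0.5, n))
    df = pd.DataFrame({
        "sample": [f"s{i}" for i in range(n)],
        "case": (latent > 1.5).astype(int),
        "age": rng.normal(55, 8, n), "sex": rng.integers(0, 2, n),
        "eosinophils": eos, "lymphocytes": lym,
    })
    truth = df["eosinophils"].copy()
    mask = rng.random(n) < miss
    df.loc[mask, "eosinophils"] = np.nan
    return df, truth, mask


def test_impute_identity_when_complete(rng):
    df, truth, mask = _cohort_with_missing(rng, miss=0.0)
    out, flags = impute_missing(df)
    pd.testing.assert_frame_equal(out, df)
    assert not flags.to_numpy().any()


def test_impute_deterministic_and_better_than_mean(rng):
    df, truth, mask = _cohort_with_missing(rng)
    out1, flags = impute_missing(df, seed=1)
    out2, _ = impute_missing(df, seed=1)
    pd.testing.assert_frame_equal(out1, out2)
    assert flags["eosinophils"].to_numpy().sum() == mask.sum()
    rmse = np.sqrt(np.mean(
        (out1.loc[mask, "eosinophils"] - truth[mask]) ** 2))
    marginal_sd = truth.std()
    assert rmse < marginal_sd


def test_impute_entirely_missing_column_errors(rng):
    df, *_ = _cohort_with_missing(rng, n=50)
    df["lymphocytes"] = np.nan
    with pytest.raises(ValueError, match="entirely missing"):
        impute_missing(df)


# --------------------------------------------------------------------------
# baseline model

def test_baseline_matches_irls_oracle(rng):
    df, *_ = _cohort_with_missing(rng, n=2000, miss=0.0)
    fit, score = fit_baseline(df)
    X = np.column_stack([
        rank_inverse_normal(df["eosinophils"]),
        rank_inverse_normal(df["lymphocytes"]),
        df["age"], df["sex"],
    ])
    beta, se = irls_logistic(df["case"].to_numpy(), X)
    np.testing.assert_allclose(fit["estimate"], beta, atol=1e-6)
    np.testing.assert_allclose(fit["se"], se, atol=1e-6)
    assert len(score.raw) == len(df)


def test_baseline_recovers_paper_signed_directions():
    cfg = SimulationConfig(n_cohort=20_000, n_ref=300, n_blocks=6,
                           block_size=10, n_tissues=1, genes_per_tissue=5,
                           seed=44)
    study = simulate_study(cfg)
    completed, _ = impute_missing(study["cohort"])
    fit, _ = fit_baseline(completed)
    fit = fit.set_index("term")
    assert fit.loc["eosinophils_int", "estimate"] > 0
    assert fit.loc["lymphocytes_int", "estimate"] < 0
    assert fit.loc["eosinophils_int", "p"] < 1e-3
    assert fit.loc["lymphocytes_int", "p"] < 1e-3


def test_baseline_requires_complete_counts(rng):
    df, *_ = _cohort_with_missing(rng, n=100, miss=0.1)
    with pytest.raises(ValueError, match="impute"):
        fit_baseline(df)


# --------------------------------------------------------------------------
# combined score

def _score_pair(rng, n=4000, r=0.3):
    # logistic generative model: no PRS x PTRS interaction by construction
    a = rng.standard_normal(n)
    b = r * a + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
    eta = -2.2 + 0.5 * a + 0.4 * b
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    cohort = pd.DataFrame({"sample": [f"s{i}" for i in range(n)], "case": y,
                           "age": rng.normal(55, 8, n),
                           "sex": rng.integers(0, 2, n)})
    s1 = ScoreVector(cohort["sample"], a, score_type="PRS", standardized=a)
    s2 = ScoreVector(cohort["sample"], b, score_type="PTRS", tissue="t0",
                     standardized=b)
    return s1, s2, cohort


def test_combine_weighted_sum_arithmetic(rng):
    s1, s2, cohort = _score_pair(rng)
    combined = combine_scores(s1, s2, cohort, covariates=["age", "sex"])
    w = combined.weights
    manual = w["prs"] * s1.values + w["ptrs"] * s2.values
    np.testing.assert_allclose(
        combined.standardized, (manual - manual.mean()) / manual.std(),
        atol=1e-10)


def test_combine_loglik_dominates_nested(rng):
    s1, s2, cohort = _score_pair(rng)
    combined = combine_scores(s1, s2, cohort, covariates=["age", "sex"])
    y = cohort["case"].to_numpy()
    base = cohort[["age", "sex"]]
    ll_joint = combined.fit.attrs["llf"]
    for single in (s1, s2):
        X = base.copy()
        X.insert(0, "score", single.values)
        ll_single = _logit_fit(y, X).attrs["llf"]
        assert ll_joint >= ll_single - 1e-6


def test_combine_rejects_collinear(rng):
    s1, s2, cohort = _score_pair(rng)
    s2b = ScoreVector(s2.samples, s1.raw.copy(), standardized=s1.values.copy())
    with pytest.raises(CollinearScoresError):
        combine_scores(s1, s2b, cohort, covariates=["age", "sex"])


# --------------------------------------------------------------------------
# interaction analyses

def test_interaction_screen_null_keeps_tissues(rng):
    s1, s2, cohort = _score_pair(rng)
    kept, report = interaction_screen(s1, {"t0": s2}, cohort,
                                      covariates=["age", "sex"])
    assert "pearson_r" in report.columns
    assert report["pearson_r"].iloc[0] == pytest.approx(0.3, abs=0.08)
    assert kept == ["t0"]


def test_biomarker_association_divisor_and_shape(rng):
    n = 1500
    s1, s2, cohort = _score_pair(rng, n=n)
    cohort["eosinophils"] = rng.lognormal(0, 0.5, n)
    cohort["lymphocytes"] = rng.lognormal(0, 0.5, n)
    for c in PC_COLUMNS:
        cohort[c] = rng.standard_normal(n)
    ptrs7 = {f"t{i}": s2 for i in range(7)}
    out = biomarker_association(cohort, s1, ptrs7)
    assert out.attrs["bonferroni_divisor"] == 21
    # both fitted variants present for every (count, tissue) pair
    assert set(out["model"]) == {"joint", "interaction"}
    joint = out[(out["model"] == "joint")]
    assert len(joint) == 2 * 7 * 2  # 2 counts x 7 tissues x 2 terms


def test_risk_interaction_matches_irls_oracle(rng):
    n = 2000
    s1, s2, cohort = _score_pair(rng, n=n)
    cohort["lymphocytes"] = rng.lognormal(0, 0.4, n)
    out = risk_interaction(cohort, {"t0": s2})
    lymph = rank_inverse_normal(cohort["lymphocytes"])
    X = np.column_stack([s2.values, lymph, s2.values * lymph,
                         cohort["age"], cohort["sex"]])
    beta, se = irls_logistic(cohort["case"].to_numpy(), X)
    assert out["estimate"].iloc[0] == pytest.approx(beta[3], abs=1e-6)
    assert out["se"].iloc[0] == pytest.approx(se[3], abs=1e-6)


def test_risk_interaction_null_pvalues_uniform():
    pvals = []
    for seed in range(12):
        rng = np.random.default_rng(500 + seed)
        s1, s2, cohort = _score_pair(rng, n=1500, r=0.0)
        cohort["lymphocytes"] = rng.lognormal(0, 0.4, 1500)
        out = risk_interaction(cohort, {"t0": s2, "t1": s1})
        pvals.extend(out["p"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
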