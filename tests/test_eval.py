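"""Stratified splitting, concordance, DeLong CIs and paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptrskit.evaluate import (
    adjusted_cstat,
    concordance,
    delong_paired,
    evaluate_suite,
    roc_auc_trapezoid,
    stratified_split,
)


def _cohort(rng, n=10_000, prev=0.04):
    return pd.DataFrame({
        "sample": [f"s{i}" for i in range(n)],
        "case": (rng.random(n) < prev).astype(int),
        "age": rng.normal(57, 8, n),
        "sex": rng.integers(0, 2, n),
    })


# --------------------------------------------------------------------------
# splitting

def test_split_preserves_stratum_fractions(rng):
    cohort = _cohort(rng)
    out = stratified_split(cohort, 0.8, seed=1)
    assert set(out["split"]) == {"train", "test"}
    # overall and per-class train fractions within rounding of 80%
    assert abs((out["split"] == "train").mean() - 0.8) < 0.01
    cases = out[out["case"] == 1]
    assert abs((cases["split"] == "train").mean() - 0.8) < 0.02
    n_cases_train = ((out["case"] == 1) & (out["split"] == "train")).sum()
    assert abs(n_cases_train - 0.8 * (out["case"] == 1).sum()) <= 10


def test_split_deterministic_and_boundary(rng):
    cohort = _cohort(rng, n=500)
    a = stratified_split(cohort, 0.8, seed=3)["split"]
    b = stratified_split(cohort, 0.8, seed=3)["split"]
    assert (a == b).all()
    with pytest.warns(UserWarning, match="empty test"):
        full = stratified_split(cohort, 1.0, seed=3)
    assert (full["split"] == "train").all()
    with pytest.raises(ValueError):
        stratified_split(cohort, 0.0, seed=3)


# --------------------------------------------------------------------------
# concordance

def test_concordance_hand_value():
    score = np.array([2.0, 3.0, 1.0, 2.5])
    y = np.array([1, 1, 0, 0])
    assert concordance(score, y) == pytest.approx(0.75)


def test_concordance_perfect_and_ties():
    y = np.array([1, 1, 0, 0])
    assert concordance(np.array([5.0, 4.0, 1.0, 2.0]), y) == 1.0
    assert concordance(np.array([1.0, 1.0, 1.0, 1.0]), y) == 0.5


def test_concordance_equals_trapezoidal_roc(rng):
    for _ in range(20):
        n = int(rng.integers(20, 200))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        score = np.round(rng.standard_normal(n), 1)  # forces ties
        assert abs(concordance(score, y)
                   - roc_auc_trapezoid(score, y)) < 1e-12


def test_monotone_transform_invariance(rng):
    y = rng.integers(0, 2, 500)
    score = rng.standard_normal(500)
    a = adjusted_cstat(score, covariates=None, y=y)
    b = adjusted_cstat(np.exp(3 * score), covariates=None, y=y)
    assert a.estimate == pytest.approx(b.estimate, abs=1e-12)


# --------------------------------------------------------------------------
# DeLong CIs

def test_null_score_ci_covers_half(rng):
    y = (rng.random(50_000) < 0.04).astype(int)
    score = rng.standard_normal(50_000)
    cs = adjusted_cstat(score, covariates=None, y=y)
    assert cs.ci_low <= 0.5 <= cs.ci_high
    assert 0.48 <= cs.estimate <= 0.52


def test_perfect_separation_c_is_one(rng):
    y = np.r_[np.ones(50), np.zeros(500)].astype(int)
    score = np.r_[rng.uniform(1, 2, 50), rng.uniform(0, 0.9, 500)]
    cs = adjusted_cstat(score, covariates=None, y=y)
    assert cs.estimate == 1.0
    assert cs.ci_high == 1.0


def test_single_class_errors(rng):
    with pytest.raises(ValueError):
        adjusted_cstat(rng.standard_normal(10), covariates=None,
                       y=np.ones(10))


def test_bootstrap_ci_close_to_delong(rng):
    n = 2000
    y = rng.integers(0, 2, n)
    score = y + rng.normal(0, 1.5, n)
    d = adjusted_cstat(score, covariates=None, y=y, method="delong")
    b = adjusted_cstat(score, covariates=None, y=y, method="bootstrap",
                       n_boot=2000, seed=1)
    assert b.ci_low == pytest.approx(d.ci_low, abs=0.01)
    assert b.ci_high == pytest.approx(d.ci_high, abs=0.01)


# --------------------------------------------------------------------------
# paired comparison

def test_delong_paired_identical_scores(rng):
    y = rng.integers(0, 2, 300)
    s = rng.standard_normal(300)
    dc = delong_paired(s, s.copy(), covariates=None, y=y)
    assert dc.delta == 0.0
    assert dc.pvalue == 1.0


def test_delong_paired_antisymmetry(rng):
    y = rng.integers(0, 2, 500)
    s1 = y + rng.normal(0, 1.0, 500)
    s2 = y + rng.normal(0, 2.0, 500)
    a = delong_paired(s1, s2, covariates=None, y=y)
    b = delong_paired(s2, s1, covariates=None, y=y)
    assert a.delta == pytest.approx(-b.delta)
    assert a.pvalue == pytest.approx(b.pvalue)


def test_delong_paired_mismatched_samples(rng):
    with pytest.raises(ValueError, match="identical samples"):
        delong_paired(np.zeros(10), np.zeros(11), covariates=None,
                      y=np.zeros(10))


def test_delong_se_matches_paired_bootstrap_oracle():
    rng = np.random.default_rng(77)
    n = 5000
    y = (rng.random(n) < 0.2).astype(int)
    s1 = y + rng.normal(0, 1.2, n)
    s2 = 0.7 * s1 + rng.normal(0, 1.0, n)
    dc = delong_paired(s1, s2, covariates=None, y=y)
    se_delong = (dc.ci_high - dc.delta) / 1.959963984540054
    deltas = np.empty(2000)
    for b in range(2000):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            deltas[b] = np.nan
            continue
        deltas[b] = concordance(s1[idx], yb) - concordance(s2[idx], yb)
    se_boot = np.nanstd(deltas)
    assert abs(se_delong - se_boot) / se_boot < 0.10


# --------------------------------------------------------------------------
# suite

def test_suite_row_count_and_null_coverage(rng):
    cohort = _cohort(rng, n=4000, prev=0.1)
    scores = {f"m{i}": rng.standard_normal(4000) for i in range(3)}
    suite = evaluate_suite(scores, cohort, covariates=None)
    assert len(suite.models) == 3
    assert (suite.models["c"] - 0.5).abs().max() < 0.05
    assert (suite.models["ci_low"] < suite.models["ci_high"]).all()
    assert len(suite.comparisons) == 3  # all unordered pairs
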