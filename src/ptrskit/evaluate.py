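"""Cohort splitting and ROC-based evaluation.

The c-statistic is the Mann-Whitney concordance (ties count one half) and
always equals the trapezoidal area under the empirical ROC curve.
Confidence intervals come from DeLong's structural-component variance
estimator by default, with a stratified-bootstrap alternative; paired
comparisons of two correlated ROC curves use the same components.
Covariate adjustment follows the fitted-probability convention: the
predictor is the linear predictor of a logistic model of case status on
score plus covariates (a residualization mode is also provided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .datatypes import DEFAULT_COVARIATES, ScoreVector

logger = logging.getLogger(__name__)


@dataclass
class CStat:
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n_cases: int
    n_controls: int


@dataclass
class DeltaC:
    delta: float
    ci_low: float
    ci_high: float
    pvalue: float


# ---------------------------------------------------------------------------
# splitting

def stratified_split(cohort: pd.DataFrame, train_fraction: float = 0.8,
                     seed: int = 0, n_age_bins: int = 5) -> pd.DataFrame:
    """Assign train/test labels stratified on case status, sex and age
    quintile, preserving the train fraction within every stratum."""
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must lie in (0, 1]")
    if train_fraction == 1:
        import warnings
        warnings.warn("train_fraction=1 leaves an empty test set", stacklevel=2)
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    age_bin = pd.qcut(out["age"], q=n_age_bins, labels=False, duplicates="drop")
    strata = (out["case"].astype(str) + "_" + out["sex"].astype(str)
              + "_" + age_bin.astype(str))
    # merge singleton strata into their (case, sex) neighbor
    counts = strata.value_counts()
    small = counts[counts < 2].index
    if len(small):
        logger.info("merged %d singleton strata with neighbors", len(small))
        strata = strata.where(~strata.isin(small),
                              out["case"].astype(str) + "_" + out["sex"].astype(str))
    split = np.empty(len(out), dtype=object)
    for _, idx in out.groupby(strata, sort=True).groups.items():
        loc = out.index.get_indexer(idx)
        perm = rng.permutation(len(loc))
        n_train = int(round(train_fraction * len(loc)))
        split[loc[perm[:n_train]]] = "train"
        split[loc[perm[n_train:]]] = "test"
    out["split"] = split
    return out


# ---------------------------------------------------------------------------
# concordance / DeLong machinery

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def concordance(score: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney concordance with half-credit for ties."""
    score = np.asarray(score, float)
    y = np.asarray(y)
    pos = score[y == 1]
    neg = score[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("outcome must contain both classes")
    r = _midrank(np.concatenate([pos, neg]))
    return (r[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """AUCs and the DeLong covariance matrix for k scores on one sample.

    ``scores`` is (k, n). Returns (aucs, cov) where cov is S10/m + S01/n
    built from case and control placement values (Sun & Xu midranks).
    """
    y = np.asarray(y)
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        all_r = np.concatenate([pos[r], neg[r]])
        tz = _midrank(all_r)
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    cov = s10 / m + s01 / n
    return aucs, np.atleast_2d(cov)


def linear_predictor(score: np.ndarray, y: np.ndarray | None,
                     covariates: pd.DataFrame | None,
                     coefs: np.ndarray | None = None):
    """Linear predictor of logistic(case ~ score + covariates).

    With ``coefs`` given (from a training fit) no model is fitted and the
    coefficients transport; otherwise the model is fitted on (score, y,
    covariates) and the fitted coefficients are returned alongside.
    """
    score = np.asarray(score, float)
    if covariates is None or covariates.shape[1] == 0:
        X = score[:, None]
    else:
        X = np.column_stack([score, covariates.to_numpy(float)])
    if coefs is None:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000,
                                 tol=1e-8)
        clf.fit(X, y)
        coefs = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    lp = coefs[0] + X @ coefs[1:]
    return lp, coefs


def quick_adjusted_auc(score: np.ndarray, y: np.ndarray,
                       covariates: pd.DataFrame | None) -> float:
    """Point covariate-adjusted AUC, used inside threshold searches."""
    if covariates is None or covariates.shape[1] == 0:
        return concordance(score, y)
    X = np.column_stack([np.asarray(score, float), covariates.to_numpy(float)])
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200,
                             tol=1e-4)
    clf.fit(X, y)
    return concordance(clf.decision_function(X), y)


def adjusted_cstat(score, cohort: pd.DataFrame | None = None,
                   covariates=DEFAULT_COVARIATES, method: str = "delong",
                   n_boot: int = 10_000, seed: int = 0,
                   coefs: np.ndarray | None = None,
                   mode: str = "fitted_prob",
                   y: np.ndarray | None = None,
                   alpha: float = 0.95) -> CStat:
    """Covariate-adjusted c-statistic with a 95% CI.

    ``score`` is a ScoreVector or array; ``cohort`` supplies the ``case``
    outcome and covariate columns (or pass ``y``/``covariates=None`` for an
    unadjusted c). ``mode='fitted_prob'`` uses the logistic linear
    predictor of case ~ score + covariates; ``mode='residual'`` residualizes
    the score on the covariates instead. CI by DeLong's analytic variance
    or stratified bootstrap.
    """
    vals = score.values if isinstance(score, ScoreVector) else np.asarray(score, float)
    if y is None:
        y = cohort["case"].to_numpy()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    cov_df = None
    if covariates is not None and cohort is not None:
        cols = [c for c in covariates if c in cohort.columns]
        cov_df = cohort[cols] if cols else None
    if cov_df is None:
        predictor = vals
    elif mode == "fitted_prob":
        predictor, _ = linear_predictor(vals, y, cov_df, coefs=coefs)
    elif mode == "residual":
        Xc = np.column_stack([np.ones(len(vals)), cov_df.to_numpy(float)])
        beta, *_ = np.linalg.lstsq(Xc, vals, rcond=None)
        predictor = vals - Xc @ beta
    else:
        raise ValueError(f"unknown adjustment mode {mode!r}")

    m, n = int((y == 1).sum()), int((y == 0).sum())
    zq = stats.norm.ppf(0.5 + alpha / 2)
    if method == "delong":
        aucs, cov = _delong_components(predictor[None, :], y)
        se = float(np.sqrt(max(cov[0, 0], 0.0)))
        est = float(aucs[0])
        lo, hi = max(est - zq * se, 0.0), min(est + zq * se, 1.0)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        est = concordance(predictor, y)
        pos = predictor[y == 1]
        neg = predictor[y == 0]
        draws = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(0, m, m)]
            bn = neg[rng.integers(0, n, n)]
            draws[b] = concordance(np.concatenate([bp, bn]),
                                   np.concatenate([np.ones(m), np.zeros(n)]))
        lo, hi = np.quantile(draws, [0.5 - alpha / 2, 0.5 + alpha / 2])
        est = float(est)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return CStat(est, float(lo), float(hi), method, m, n)


def delong_paired(score1, score2, cohort: pd.DataFrame | None = None,
                  covariates=DEFAULT_COVARIATES,
                  y: np.ndarray | None = None,
                  coefs1=None, coefs2=None) -> DeltaC:
    """Paired DeLong comparison of two (covariate-adjusted) ROC curves."""
    v1 = score1.values if isinstance(score1, ScoreVector) else np.asarray(score1, float)
    v2 = score2.values if isinstance(score2, ScoreVector) else np.asarray(score2, float)
    if len(v1) != len(v2):
        raise ValueError("scores must be computed on identical samples")
    if y is None:
        y = cohort["case"].to_numpy()
    y = np.asarray(y)
    cov_df = None
    if covariates is not None and cohort is not None:
        cols = [c for c in covariates if c in cohort.columns]
        cov_df = cohort[cols] if cols else None
    if cov_df is not None:
        v1, _ = linear_predictor(v1, y, cov_df, coefs=coefs1)
        v2, _ = linear_predictor(v2, y, cov_df, coefs=coefs2)
    aucs, cov = _delong_components(np.vstack([v1, v2]), y)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        return DeltaC(delta, delta, delta, 1.0)
    se = np.sqrt(var)
    z = delta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return DeltaC(delta, delta - 1.959963984540054 * se,
                  delta + 1.959963984540054 * se, p)


def roc_auc_trapezoid(score: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal area under the empirical ROC curve (independent of the
    rank-based concordance path; used as a cross-check)."""
    score = np.asarray(score, float)
    y = np.asarray(y)
    order = np.argsort(score, kind="mergesort")[::-1]
    y_sorted = y[order]
    s_sorted = score[order]
    m = (y == 1).sum()
    n = (y == 0).sum()
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # collapse tied thresholds to one ROC vertex
    distinct = np.nonzero(np.diff(s_sorted))[0]
    keep = np.r_[distinct, len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[keep] / m]
    fpr = np.r_[0.0, fps[keep] / n]
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# model-suite evaluation

@dataclass
class SuiteReport:
    models: pd.DataFrame
    comparisons: pd.DataFrame


def evaluate_suite(score_dict: dict[str, np.ndarray], cohort: pd.DataFrame,
                   covariates=DEFAULT_COVARIATES, comparisons=None,
                   method: str = "delong") -> SuiteReport:
    """c-statistics with CIs for a set of named predictors plus pairwise
    DeLong comparisons.

    ``comparisons`` is a list of (name1, name2) pairs; default all pairs.
    """
    rows = []
    for name, vals in score_dict.items():
        cs = adjusted_cstat(vals, cohort, covariates, method=method)
        rows.append({"model": name, "c": cs.estimate, "ci_low": cs.ci_low,
                     "ci_high": cs.ci_high, "n_cases": cs.n_cases,
                     "n_controls": cs.n_controls})
    models = pd.DataFrame(rows)
    names = list(score_dict)
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    crows = []
    for a, b in comparisons:
        dc = delong_paired(score_dict[a], score_dict[b], cohort, covariates)
        crows.append({"model": a, "comparator": b, "delta": dc.delta,
                      "ci_low": dc.ci_low, "ci_high": dc.ci_high,
                      "p": dc.pvalue})
    return SuiteReport(models, pd.DataFrame(
        crows, columns=["model", "comparator", "delta", "ci_low", "ci_high", "p"]))
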