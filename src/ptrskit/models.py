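"""Baseline clinical risk model, combined weighted risk score, interaction
screening and biomarker association models.

Blood counts are rank-based inverse-normal transformed (Blom offset 3/8)
and missing values completed by single-imputation chained equations with a
gradient-boosted regression-tree learner. All binary-outcome models are
maximum-likelihood logistic regressions (statsmodels) reported as log-odds
with Wald 95% CIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import LinearRegression

from .datatypes import DEFAULT_COVARIATES, PC_COLUMNS, ScoreVector

logger = logging.getLogger(__name__)

BLOOD_COUNTS = ["eosinophils", "lymphocytes"]


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse normal transform; missing values stay
    missing, ties get their average rank."""
    x = np.asarray(values, float)
    out = np.full_like(x, np.nan)
    mask = np.isfinite(x)
    obs = x[mask]
    n = len(obs)
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.ptp(obs) == 0:
        warnings.warn("all non-missing values equal; transform is zero",
                      stacklevel=2)
        out[mask] = 0.0
        return out
    r = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf((r - offset) / (n + 1 - 2 * offset))
    return out


def impute_missing(cohort: pd.DataFrame, n_cycles: int = 5, seed: int = 0,
                   learner: str = "trees"
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chained-equations single imputation of the blood counts.

    Each incomplete count is iteratively regressed on age, sex, case status
    and the other count using a regression-tree ensemble (gradient-boosted
    trees; ``learner='linear'`` falls back to OLS), and its missing cells
    replaced by the prediction; cycles repeat with updated values. Returns
    the completed table and a boolean mask of imputed cells.
    """
    out = cohort.copy()
    targets = [c for c in BLOOD_COUNTS if c in out.columns and out[c].isna().any()]
    mask = pd.DataFrame(False, index=out.index,
                        columns=[c for c in BLOOD_COUNTS if c in out.columns])
    for c in mask.columns:
        mask[c] = out[c].isna()
        if out[c].isna().all():
            raise ValueError(f"column {c} is entirely missing")
    if not targets:
        return out, mask
    base_predictors = [c for c in ("age", "sex", "case") if c in out.columns]
    # initialize with marginal means
    for c in targets:
        out.loc[mask[c], c] = out[c].mean()
    for cycle in range(n_cycles):
        for c in targets:
            others = [o for o in BLOOD_COUNTS if o != c and o in out.columns]
            preds = base_predictors + others
            X = out.loc[~mask[c], preds].to_numpy(float)
            y = out.loc[~mask[c], c].to_numpy(float)
            if learner == "trees":
                model = HistGradientBoostingRegressor(
                    max_iter=50, random_state=seed + cycle)
            else:
                model = LinearRegression()
            model.fit(X, y)
            out.loc[mask[c], c] = model.predict(
                out.loc[mask[c], preds].to_numpy(float))
    return out, mask


def _logit_fit(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood logistic fit -> tidy term table."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError("IRLS did not converge")
        params = np.asarray(res.params)
        se = np.asarray(res.bse)
        llf = float(res.llf)
    except Exception:
        warnings.warn("separation or non-convergence; refit with a small "
                      "L2 penalty", stacklevel=2)
        params, se, llf = _penalized_logit(y, Xc.to_numpy(float), alpha=1e-4)
    z = 1.959963984540054
    lp = np.asarray(Xc.to_numpy(float) @ params)
    out = pd.DataFrame({
        "term": Xc.columns,
        "estimate": params,
        "se": se,
        "p": np.clip(2 * stats.norm.sf(np.abs(params / se)), 1e-300, 1.0),
        "ci_low": params - z * se,
        "ci_high": params + z * se,
    })
    out.attrs["llf"] = llf
    out.attrs["fitted_lp"] = lp
    return out


def _penalized_logit(y, X, alpha=1e-4):
    """Ridge-penalized logistic fit with Wald SEs from the penalized
    Hessian; used only when the unpenalized MLE fails (separation)."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / (2 * alpha), solver="lbfgs",
                             fit_intercept=False, max_iter=5000)
    clf.fit(X, y)
    params = clf.coef_.ravel()
    eta = X @ params
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    H = (X * W[:, None]).T @ X + 2 * alpha * np.eye(X.shape[1])
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return params, se, llf


def _ols_fit(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int()
    return pd.DataFrame({
        "term": Xc.columns,
        "estimate": np.asarray(res.params),
        "se": np.asarray(res.bse),
        "p": np.clip(np.asarray(res.pvalues), 1e-300, 1.0),
        "ci_low": np.asarray(ci)[:, 0],
        "ci_high": np.asarray(ci)[:, 1],
    })


def fit_baseline(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ScoreVector]:
    """Baseline clinical model: logistic case ~ INT(eosinophils) +
    INT(lymphocytes) + age + sex; the baseline score is the fitted linear
    predictor. Counts must be complete (impute first)."""
    for c in BLOOD_COUNTS:
        if cohort[c].isna().any():
            raise ValueError(f"{c} contains missing values; impute first")
    X = pd.DataFrame({
        "eosinophils_int": rank_inverse_normal(cohort["eosinophils"]),
        "lymphocytes_int": rank_inverse_normal(cohort["lymphocytes"]),
        "age": cohort["age"].to_numpy(float),
        "sex": cohort["sex"].to_numpy(float),
    }, index=cohort.index)
    fit = _logit_fit(cohort["case"].to_numpy(), X)
    score = ScoreVector(cohort["sample"].to_numpy(), fit.attrs["fitted_lp"],
                        score_type="baseline", n_features=4)
    return fit, score


class CollinearScoresError(ValueError):
    """PRS and PTRS are numerically collinear; combining is meaningless."""


def combine_scores(prs: ScoreVector, ptrs: ScoreVector, cohort: pd.DataFrame,
                   covariates=DEFAULT_COVARIATES,
                   train_mask: np.ndarray | None = None) -> ScoreVector:
    """Weighted-sum combination of standardized PRS and PTRS.

    Weights are the two scores' coefficients from logistic
    case ~ PRS + PTRS + covariates fitted on the training individuals;
    the combined raw score w_prs*PRS + w_ptrs*PTRS is then standardized on
    the training reference. Covariates contribute to the weight fit but not
    to the sum (they re-enter at evaluation).
    """
    from .prs import standardize

    v1, v2 = prs.values, ptrs.values
    if len(v1) != len(v2):
        raise ValueError("scores must cover identical samples")
    mask = (np.ones(len(v1), bool) if train_mask is None
            else np.asarray(train_mask))
    r = np.corrcoef(v1[mask], v2[mask])[0, 1]
    if abs(r) > 0.999:
        raise CollinearScoresError(
            f"PRS and PTRS are collinear (r={r:.4f}); use a single score")
    cols = [c for c in covariates if c in cohort.columns]
    X = pd.DataFrame({"prs": v1[mask], "ptrs": v2[mask]})
    for c in cols:
        X[c] = cohort.loc[mask, c].to_numpy(float)
    fit = _logit_fit(cohort.loc[mask, "case"].to_numpy(), X)
    w = fit.set_index("term")["estimate"]
    raw = w["prs"] * v1 + w["ptrs"] * v2
    combined = ScoreVector(prs.samples, raw, score_type="combined",
                           n_features=2, tissue=ptrs.tissue)
    combined = standardize(combined, reference=mask)
    combined.weights = {"prs": float(w["prs"]), "ptrs": float(w["ptrs"])}
    combined.fit = fit
    return combined


def interaction_screen(prs: ScoreVector, ptrs_by_tissue: dict[str, ScoreVector],
                       cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                       alpha: float = 0.05,
                       train_mask: np.ndarray | None = None
                       ) -> tuple[list[str], pd.DataFrame]:
    """Keep tissues whose PRS x PTRS interaction is non-significant.

    Per tissue: logistic case ~ PRS + PTRS + PRS*PTRS + covariates on the
    training individuals; tissues with interaction P below the Bonferroni
    threshold alpha/n_tissues are excluded from combination. The report
    also carries the Pearson correlation between the scores.
    """
    mask = (np.ones(len(prs.values), bool) if train_mask is None
            else np.asarray(train_mask))
    cols = [c for c in covariates if c in cohort.columns]
    n_tissues = len(ptrs_by_tissue)
    thr = alpha / n_tissues
    rows, kept = [], []
    v1 = prs.values[mask]
    y = cohort.loc[mask, "case"].to_numpy()
    for tissue, ptrs in ptrs_by_tissue.items():
        v2 = ptrs.values[mask]
        X = pd.DataFrame({"prs": v1, "ptrs": v2, "prs_x_ptrs": v1 * v2})
        for c in cols:
            X[c] = cohort.loc[mask, c].to_numpy(float)
        fit = _logit_fit(y, X)
        p_int = float(fit.set_index("term").loc["prs_x_ptrs", "p"])
        r = float(np.corrcoef(v1, v2)[0, 1])
        keep = p_int >= thr
        rows.append({"tissue": tissue, "pearson_r": r,
                     "interaction_estimate": float(
                         fit.set_index("term").loc["prs_x_ptrs", "estimate"]),
                     "interaction_p": p_int, "kept": keep})
        if keep:
            kept.append(tissue)
    return kept, pd.DataFrame(rows)


def biomarker_association(cohort: pd.DataFrame, prs: ScoreVector,
                          ptrs_by_tissue: dict[str, ScoreVector],
                          alpha: float = 0.05,
                          bonferroni_divisor: int | None = None,
                          include_interaction: bool = True) -> pd.DataFrame:
    """Linear models of INT blood counts on PRS, PTRS and their product.

    Per (count, tissue): INT(count) ~ PRS + PTRS [+ PRS*PTRS] + age + sex +
    PC1..10, fitted on the given (test) cohort rows with non-missing
    counts. The Bonferroni divisor defaults to n_tissues x 3 score terms.
    Both the interaction variant and the joint two-score variant are
    reported (column ``model``).
    """
    if bonferroni_divisor is None:
        bonferroni_divisor = 3 * len(ptrs_by_tissue)
    thr = alpha / bonferroni_divisor
    covs = ["age", "sex"] + [c for c in PC_COLUMNS if c in cohort.columns]
    rows = []
    for count in BLOOD_COUNTS:
        yv = rank_inverse_normal(cohort[count])
        ok = np.isfinite(yv)
        for tissue, ptrs in ptrs_by_tissue.items():
            v1 = prs.values[ok]
            v2 = ptrs.values[ok]
            variants = [("joint", {"prs": v1, "ptrs": v2})]
            if include_interaction:
                variants.append(("interaction",
                                 {"prs": v1, "ptrs": v2, "prs_x_ptrs": v1 * v2}))
            for label, terms in variants:
                X = pd.DataFrame(terms)
                for c in covs:
                    X[c] = cohort.loc[ok, c].to_numpy(float)
                fit = _ols_fit(yv[ok], X)
                for term in terms:
                    row = fit.set_index("term").loc[term]
                    rows.append({
                        "outcome": count, "tissue": tissue, "model": label,
                        "term": term, "estimate": row["estimate"],
                        "se": row["se"], "p": row["p"],
                        "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                        "significant": row["p"] <= thr,
                    })
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_divisor"] = bonferroni_divisor
    return out


def risk_interaction(cohort: pd.DataFrame,
                     ptrs_by_tissue: dict[str, ScoreVector],
                     alpha: float = 0.05) -> pd.DataFrame:
    """PTRS x lymphocyte interaction in disease risk.

    Per tissue: logistic case ~ PTRS + INT(lymph) + PTRS*INT(lymph) + age +
    sex + PCs; interaction estimates Bonferroni-corrected over tissues.
    """
    lymph = rank_inverse_normal(cohort["lymphocytes"])
    if not np.isfinite(lymph).all():
        raise ValueError("lymphocyte counts must be complete; impute first")
    covs = ["age", "sex"] + [c for c in PC_COLUMNS if c in cohort.columns]
    thr = alpha / len(ptrs_by_tissue)
    y = cohort["case"].to_numpy()
    rows = []
    for tissue, ptrs in ptrs_by_tissue.items():
        v = ptrs.values
        X = pd.DataFrame({"ptrs": v, "lymph_int": lymph,
                          "ptrs_x_lymph": v * lymph})
        for c in covs:
            X[c] = cohort[c].to_numpy(float)
        fit = _logit_fit(y, X)
        row = fit.set_index("term").loc["ptrs_x_lymph"]
        rows.append({"tissue": tissue, "estimate": row["estimate"],
                     "se": row["se"], "p": row["p"],
                     "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                     "significant": row["p"] < thr})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator wrappers

class BaselineRiskModel(BaseEstimator):
    """Clinical baseline: INT blood counts + age + sex logistic model."""

    def __init__(self, n_impute_cycles: int = 5, seed: int = 0):
        self.n_impute_cycles = n_impute_cycles
        self.seed = seed

    def fit(self, cohort: pd.DataFrame) -> "BaselineRiskModel":
        completed, _ = impute_missing(cohort, self.n_impute_cycles, self.seed)
        self.fit_, score = fit_baseline(completed)
        self.coef_ = self.fit_.set_index("term")["estimate"]
        return self

    def transform(self, cohort: pd.DataFrame) -> ScoreVector:
        completed, _ = impute_missing(cohort, self.n_impute_cycles, self.seed)
        X = pd.DataFrame({
            "const": 1.0,
            "eosinophils_int": rank_inverse_normal(completed["eosinophils"]),
            "lymphocytes_int": rank_inverse_normal(completed["lymphocytes"]),
            "age": completed["age"].to_numpy(float),
            "sex": completed["sex"].to_numpy(float),
        })
        lp = X.to_numpy(float) @ self.coef_.loc[X.columns].to_numpy(float)
        return ScoreVector(completed["sample"].to_numpy(), lp,
                           score_type="baseline", n_features=4)


class CombinedRiskScore(BaseEstimator):
    """Weighted-sum combination of two standardized scores."""

    def __init__(self, covariates: tuple = tuple(DEFAULT_COVARIATES)):
        self.covariates = covariates

    def fit(self, prs: ScoreVector, ptrs: ScoreVector, cohort: pd.DataFrame,
            train_mask: np.ndarray | None = None) -> "CombinedRiskScore":
        combined = combine_scores(prs, ptrs, cohort, list(self.covariates),
                                  train_mask)
        self.weights_ = combined.weights
        self.mu_, self.sigma_ = combined.mu, combined.sigma
        self.score_ = combined
        return self

    def transform(self, prs: ScoreVector, ptrs: ScoreVector) -> ScoreVector:
        from .prs import standardize

        raw = (self.weights_["prs"] * prs.values
               + self.weights_["ptrs"] * ptrs.values)
        sc = ScoreVector(prs.samples, raw, score_type="combined",
                         n_features=2, tissue=ptrs.tissue)
        return standardize(sc, reference=(self.mu_, self.sigma_))
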