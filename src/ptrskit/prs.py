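"""Clumping-and-thresholding polygenic risk score.

Scores are additive dosage-times-beta sums over clumped variants passing a
P-value cutoff; the cutoff is chosen on the training set by maximal
covariate-adjusted AUC over a geometric candidate grid, and scores are
standardized to zero mean / unit (population) SD on the training reference
before transport to any other sample set.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import GenotypePanel, ScoreVector

logger = logging.getLogger(__name__)


class DegenerateScoreError(ValueError):
    """A score is constant on its standardization reference."""


def default_threshold_grid(n_points: int = 200, p_min: float = 5e-8,
                           p_max: float = 1.0) -> np.ndarray:
    """High-resolution geometric grid of candidate P-value cutoffs."""
    return np.geomspace(p_min, p_max, n_points)


def _mean_imputed(dosages: np.ndarray) -> np.ndarray:
    if not np.isnan(dosages).any():
        return dosages
    X = dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    mask = np.isnan(X)
    X[mask] = np.take(col_mean, np.where(mask)[1])
    return X


def score_prs(panel: GenotypePanel, stats_df: pd.DataFrame,
              retained: pd.DataFrame, p_threshold: float) -> ScoreVector:
    """raw_i = sum over retained variants with P <= threshold of
    beta_l * X_il; missing dosages are mean-imputed per variant."""
    passing = retained.loc[retained["p"] <= p_threshold]
    if len(passing) == 0:
        warnings.warn("no variants pass the P-value threshold; PRS is zero",
                      stacklevel=2)
        return ScoreVector(panel.samples, np.zeros(panel.n_samples),
                           score_type="PRS", threshold=p_threshold,
                           n_features=0)
    idx = panel.variant_index().get_indexer(passing["id"])
    present = idx >= 0
    if not present.all():
        logger.info("score_prs: %d retained variants absent from scoring "
                    "panel", int((~present).sum()))
    idx = idx[present]
    beta = passing["beta"].to_numpy(float)[present]
    X = _mean_imputed(panel.dosages[:, idx])
    raw = X @ beta
    return ScoreVector(panel.samples, raw, score_type="PRS",
                       threshold=p_threshold, n_features=int(present.sum()))


def standardize(score: ScoreVector, reference=None) -> ScoreVector:
    """Standardize a score using a declared reference.

    ``reference`` is either a boolean mask / index array selecting the
    reference individuals (default: all), or a precomputed ``(mu, sigma)``
    pair to transport from another set. Population (ddof=0) SD.
    """
    if isinstance(reference, tuple):
        mu, sigma = reference
    else:
        ref_vals = score.raw if reference is None else score.raw[np.asarray(reference)]
        mu = float(np.mean(ref_vals))
        sigma = float(np.std(ref_vals))
    if sigma <= 0:
        raise DegenerateScoreError("score is constant on its reference set")
    return ScoreVector(
        score.samples, score.raw, score_type=score.score_type,
        threshold=score.threshold, n_features=score.n_features,
        tissue=score.tissue, standardized=(score.raw - mu) / sigma,
        mu=mu, sigma=sigma,
    )


def threshold_search(panel: GenotypePanel, stats_df: pd.DataFrame,
                     retained: pd.DataFrame, candidate_thresholds,
                     outcome: np.ndarray, covariates: pd.DataFrame | None = None,
                     train_mask: np.ndarray | None = None
                     ) -> tuple[ScoreVector, pd.DataFrame]:
    """Select the P-value cutoff maximizing the covariate-adjusted training
    AUC. Ties break toward the smaller threshold. Returns the best raw
    score (on all panel samples) and the per-threshold report."""
    from .evaluate import quick_adjusted_auc

    candidate_thresholds = np.sort(np.asarray(list(candidate_thresholds), float))
    if len(candidate_thresholds) == 0:
        raise ValueError("candidate_thresholds must be nonempty")
    y = np.asarray(outcome)
    if train_mask is None:
        train_mask = np.ones(panel.n_samples, dtype=bool)
    y_train = y[train_mask]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training outcome must contain both classes")

    # sort variants by P once; every threshold is a prefix of this order,
    # so all candidate scores come from one cumulative sum
    order = retained.sort_values(["p", "pos", "id"], kind="mergesort")
    idx = panel.variant_index().get_indexer(order["id"])
    present = idx >= 0
    order = order.loc[present]
    idx = idx[present]
    X = _mean_imputed(panel.dosages[:, idx])
    weighted = X * order["beta"].to_numpy(float)
    cum = np.cumsum(weighted, axis=1) if weighted.shape[1] else weighted
    p_sorted = order["p"].to_numpy(float)

    cov_train = covariates.loc[train_mask] if covariates is not None else None
    report = []
    best = (-np.inf, None)
    for t in candidate_thresholds:
        k = int(np.searchsorted(p_sorted, t, side="right"))
        raw = cum[:, k - 1] if k > 0 else np.zeros(panel.n_samples)
        if k == 0 or np.std(raw[train_mask]) == 0:
            auc = 0.5
        else:
            auc = quick_adjusted_auc(raw[train_mask], y_train, cov_train)
        report.append({"threshold": t, "n_features": k, "c_statistic": auc})
        if auc > best[0]:       # strict: ties keep the smaller threshold
            best = (auc, t)
    best_t = best[1]
    best_score = score_prs(panel, stats_df, retained, best_t)
    return best_score, pd.DataFrame(report)


class ClumpThresholdPRS(BaseEstimator):
    """sklearn-style C+T PRS model.

    fit() clumps harmonized summary statistics against a reference panel,
    searches the P-value threshold grid by maximal covariate-adjusted AUC
    on the training individuals, and freezes the selected variant weights
    and the training standardization constants. transform() scores any
    genotype panel with those frozen parameters.
    """

    def __init__(self, r2_max: float = 0.1, window_kb: float = 250.0,
                 grid_size: int = 200, thresholds=None):
        self.r2_max = r2_max
        self.window_kb = window_kb
        self.grid_size = grid_size
        self.thresholds = thresholds

    def fit(self, panel: GenotypePanel, stats_df: pd.DataFrame,
            outcome: np.ndarray, covariates: pd.DataFrame | None = None,
            ld_panel: GenotypePanel | None = None,
            train_mask: np.ndarray | None = None) -> "ClumpThresholdPRS":
        from .ld import clump

        ld_panel = panel if ld_panel is None else ld_panel
        retained = clump(stats_df, ld_panel, r2_max=self.r2_max,
                         window_kb=self.window_kb)
        grid = (default_threshold_grid(self.grid_size)
                if self.thresholds is None else self.thresholds)
        best, report = threshold_search(
            panel, stats_df, retained, grid, outcome, covariates, train_mask
        )
        mask = (np.ones(panel.n_samples, bool) if train_mask is None
                else np.asarray(train_mask))
        std = standardize(best, reference=mask)
        self.retained_ = retained
        self.best_threshold_ = best.threshold
        self.n_features_ = best.n_features
        self.report_ = report
        self.mu_, self.sigma_ = std.mu, std.sigma
        self.weights_ = retained.loc[retained["p"] <= best.threshold,
                                     ["id", "ea", "oa", "beta", "p"]]
        return self

    def transform(self, panel: GenotypePanel) -> ScoreVector:
        score = score_prs(panel, None, self.retained_, self.best_threshold_)
        return standardize(score, reference=(self.mu_, self.sigma_))
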