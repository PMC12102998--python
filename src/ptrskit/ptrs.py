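"""Tissue-specific polygenic transcriptome risk scores.

PTRS_i = sum over genes with TWAS P <= threshold of T_ig * beta_g, over a
fixed grid of nine gene-level P-value cutoffs; the per-tissue model is the
cutoff maximizing covariate-adjusted training AUC, with AUC ties broken
toward the more stringent cutoff (fewer genes).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import ScoreVector
from .twas import GrexMatrix

#: the fixed gene P-value threshold grid, loosest to tightest
PTRS_THRESHOLDS = (1.0, 0.1, 5e-2, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 1e-7)


def compute_ptrs(grex: GrexMatrix, assoc: pd.DataFrame,
                 p_threshold: float) -> ScoreVector:
    """Sum of predicted expression times gene effect over genes passing the
    TWAS P-value cutoff."""
    matched = assoc.loc[assoc["gene"].isin(grex.genes)]
    passing = matched.loc[matched["pvalue"] <= p_threshold]
    if len(passing) == 0:
        warnings.warn("no genes pass the P-value threshold; PTRS is zero",
                      stacklevel=2)
        return ScoreVector(grex.samples, np.zeros(len(grex.samples)),
                           score_type="PTRS", threshold=p_threshold,
                           n_features=0, tissue=grex.tissue)
    cols = [grex.genes.index(g) for g in passing["gene"]]
    raw = grex.values[:, cols] @ passing["effect"].to_numpy(float)
    return ScoreVector(grex.samples, raw, score_type="PTRS",
                       threshold=p_threshold, n_features=int(len(passing)),
                       tissue=grex.tissue)


def ptrs_grid(grex: GrexMatrix, assoc: pd.DataFrame,
              thresholds=PTRS_THRESHOLDS) -> list[ScoreVector]:
    """One PTRS per cutoff of the fixed threshold grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [compute_ptrs(grex, assoc, t) for t in thresholds]


def select_best_ptrs(grids: dict[str, list[ScoreVector]], outcome: np.ndarray,
                     covariates: pd.DataFrame | None = None,
                     train_mask: np.ndarray | None = None
                     ) -> tuple[dict[str, ScoreVector], pd.DataFrame]:
    """Per tissue, the threshold maximizing covariate-adjusted training AUC.

    ``grids`` maps tissue -> list of ScoreVector (as from ptrs_grid).
    Returns the selected raw score per tissue plus a report of every
    (tissue, threshold, n_features, c_statistic) evaluated, with the
    selected rows flagged.
    """
    from .evaluate import quick_adjusted_auc

    y = np.asarray(outcome)
    rows = []
    best = {}
    for tissue, scores in grids.items():
        if not scores:
            raise ValueError(f"empty PTRS grid for tissue {tissue}")
        mask = (np.ones(len(scores[0].raw), bool) if train_mask is None
                else np.asarray(train_mask))
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError("training outcome must contain both classes")
        cov_train = covariates.loc[mask] if covariates is not None else None
        best_auc, best_score = -np.inf, None
        # iterate tightest-first so AUC ties resolve toward fewer genes
        for sc in sorted(scores, key=lambda s: s.threshold):
            raw_train = sc.raw[mask]
            auc = (0.5 if np.std(raw_train) == 0
                   else quick_adjusted_auc(raw_train, y_train, cov_train))
            rows.append({"tissue": tissue, "threshold": sc.threshold,
                         "n_features": sc.n_features, "c_statistic": auc})
            if auc > best_auc:
                best_auc, best_score = auc, sc
        best[tissue] = best_score
    report = pd.DataFrame(rows)
    report["selected"] = [
        best[r.tissue].threshold == r.threshold for r in report.itertuples()
    ]
    return best, report


class TranscriptomePTRS(BaseEstimator):
    """sklearn-style per-tissue PTRS model.

    fit() computes the threshold grid from a GReX matrix and TWAS gene
    associations on the training individuals, selects the maximal-AUC
    cutoff, and freezes the gene effects and training standardization.
    transform() scores any GReX matrix of the same tissue.
    """

    def __init__(self, thresholds=PTRS_THRESHOLDS):
        self.thresholds = thresholds

    def fit(self, grex: GrexMatrix, assoc: pd.DataFrame, outcome: np.ndarray,
            covariates: pd.DataFrame | None = None,
            train_mask: np.ndarray | None = None) -> "TranscriptomePTRS":
        from .prs import standardize

        grid = ptrs_grid(grex, assoc, self.thresholds)
        best, report = select_best_ptrs({grex.tissue: grid}, outcome,
                                        covariates, train_mask)
        sc = best[grex.tissue]
        mask = (np.ones(len(grex.samples), bool) if train_mask is None
                else np.asarray(train_mask))
        std = standardize(sc, reference=mask)
        self.tissue_ = grex.tissue
        self.best_threshold_ = sc.threshold
        self.n_features_ = sc.n_features
        self.report_ = report
        self.mu_, self.sigma_ = std.mu, std.sigma
        self.assoc_ = assoc.loc[assoc["pvalue"] <= sc.threshold,
                                ["gene", "effect", "pvalue"]]
        return self

    def transform(self, grex: GrexMatrix) -> ScoreVector:
        from .prs import standardize

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = compute_ptrs(
                grex,
                self.assoc_.assign(tissue=self.tissue_),
                self.best_threshold_ if self.best_threshold_ is not None else 1.0,
            )
        return standardize(sc, reference=(self.mu_, self.sigma_))
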