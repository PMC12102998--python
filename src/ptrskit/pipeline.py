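"""End-to-end orchestration: simulate -> harmonize -> clump -> TWAS -> PRS
-> PTRS -> baseline -> combine -> evaluate.

Every stage consumes the previous stage's artifacts; all randomness flows
from the SimulationConfig seed, so a fixed configuration reproduces the
whole run bit for bit. Test-set evaluation transports training-fitted
coefficients (covariate adjustment and combination weights) to the test
individuals rather than refitting there.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_COVARIATES
from .evaluate import evaluate_suite, linear_predictor, stratified_split
from .ld import compute_ld_blocks
from .models import BaselineRiskModel, combine_scores, interaction_screen
from .prs import ClumpThresholdPRS
from .ptrs import TranscriptomePTRS
from .simulate import SimulationConfig, simulate_study
from .io import harmonize, qc_filter
from .twas import predict_grex, spredixcan

logger = logging.getLogger(__name__)


def _transported_lp(terms_train: np.ndarray, y_train: np.ndarray,
                    terms_test: np.ndarray):
    """Fit logistic on train terms, return the test linear predictor."""
    import pandas as _pd
    _, coefs = linear_predictor(
        terms_train[:, 0], y_train,
        _pd.DataFrame(terms_train[:, 1:]) if terms_train.shape[1] > 1 else None,
    )
    X_te = terms_test
    lp_te = coefs[0] + X_te @ coefs[1:]
    return lp_te, coefs


def run_pipeline(config: SimulationConfig, grid_size: int = 200,
                 include_baseline: bool = True,
                 covariates=DEFAULT_COVARIATES) -> dict:
    """Run the full risk-score study on one synthetic cohort.

    Returns a dict with the generator artifacts, the fitted score models,
    per-stage reports and the test-set evaluation suite.
    """
    study = simulate_study(config)
    cohort = stratified_split(study["cohort"], config.train_fraction,
                              seed=config.seed)
    train = (cohort["split"] == "train").to_numpy()
    test = ~train
    y = cohort["case"].to_numpy()
    cov_df = cohort[[c for c in covariates if c in cohort.columns]]

    stats_df = qc_filter(study["sumstats"], maf_min=0.01)
    stats_df = harmonize(stats_df, study["reference_panel"].variants)
    ld_blocks = compute_ld_blocks(study["reference_panel"])

    # --- PRS ---------------------------------------------------------------
    prs_model = ClumpThresholdPRS(grid_size=grid_size)
    prs_model.fit(study["cohort_panel"], stats_df, y, cov_df,
                  ld_panel=study["reference_panel"], train_mask=train)
    prs = prs_model.transform(study["cohort_panel"])

    # --- TWAS + PTRS per tissue --------------------------------------------
    ptrs_models, ptrs_scores, assoc_tables = {}, {}, {}
    for model in study["weight_models"]:
        grex = predict_grex(study["cohort_panel"], model)
        assoc = spredixcan(stats_df, model, ld_blocks)
        assoc_tables[model.tissue] = assoc
        pm = TranscriptomePTRS()
        pm.fit(grex, assoc, y, cov_df, train_mask=train)
        ptrs_models[model.tissue] = pm
        ptrs_scores[model.tissue] = pm.transform(grex)

    # --- interaction screen + combination ----------------------------------
    kept, screen_report = interaction_screen(
        prs, ptrs_scores, cohort, covariates, train_mask=train)
    combined = {}
    for tissue in kept:
        try:
            combined[tissue] = combine_scores(
                prs, ptrs_scores[tissue], cohort, covariates, train_mask=train)
        except ValueError as exc:
            logger.warning("skipping combination for %s: %s", tissue, exc)

    # --- baseline ----------------------------------------------------------
    baseline = None
    if include_baseline:
        bl_model = BaselineRiskModel(seed=config.seed)
        bl_model.fit(cohort.loc[train])
        baseline = bl_model.transform(cohort)

    # --- evaluation on the test set ----------------------------------------
    y_tr, y_te = y[train], y[test]
    cov_tr = cov_df.loc[train].to_numpy(float)
    cov_te = cov_df.loc[test].to_numpy(float)

    def transported(*score_arrays):
        tr = np.column_stack([s[train] for s in score_arrays] + [cov_tr])
        te = np.column_stack([s[test] for s in score_arrays] + [cov_te])
        lp, _ = _transported_lp(tr, y_tr, te)
        return lp

    predictors = {"prs": transported(prs.values)}
    for tissue, sc in ptrs_scores.items():
        predictors[f"ptrs_{tissue}"] = transported(sc.values)
    for tissue, sc in combined.items():
        predictors[f"combined_{tissue}"] = transported(sc.values)
    if baseline is not None:
        predictors["baseline"] = transported(baseline.raw)
        predictors["baseline_plus_prs"] = transported(baseline.raw, prs.values)
        for tissue, sc in combined.items():
            predictors[f"baseline_plus_combined_{tissue}"] = transported(
                baseline.raw, sc.values)

    comparisons = [("prs", k) for k in predictors if k.startswith("ptrs_")]
    comparisons += [(k, "prs") for k in predictors if k.startswith("combined_")]
    suite = evaluate_suite(
        {k: v for k, v in predictors.items()},
        cohort.loc[test].reset_index(drop=True),
        covariates=None, comparisons=comparisons,
    )

    return {
        "config": config,
        "study": study,
        "cohort": cohort,
        "train_mask": train,
        "sumstats": stats_df,
        "prs_model": prs_model,
        "prs": prs,
        "assoc_tables": assoc_tables,
        "ptrs_models": ptrs_models,
        "ptrs_scores": ptrs_scores,
        "interaction_screen": screen_report,
        "kept_tissues": kept,
        "combined": combined,
        "baseline": baseline,
        "predictors": predictors,
        "suite": suite,
    }


def pipeline_fingerprint(result: dict) -> str:
    """Stable hash of the pipeline's numeric outputs, for determinism
    checks."""
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(result["prs"].values).tobytes())
    for tissue in sorted(result["ptrs_scores"]):
        h.update(np.ascontiguousarray(
            result["ptrs_scores"][tissue].values).tobytes())
    h.update(result["suite"].models.round(12).to_csv().encode())
    h.update(result["suite"].comparisons.round(12).to_csv().encode())
    return h.hexdigest()
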