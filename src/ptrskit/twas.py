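"""Genetically regulated expression (GReX) and summary-level gene
association.

GReX is the linear prediction T_ig = sum_l w_lg X_il with dosages counted
on each weight's effect allele. The summary-level gene z-score combines
per-variant GWAS z-scores, eQTL weights and reference LD:

    z_g = sum_l w_lg (sigma_l / sigma_g) z_l,     sigma_g^2 = w' Sigma w

with Sigma the reference dosage covariance of the model's variants; the
gene effect per unit predicted expression is
beta_g = sum_l w_lg sigma_l^2 beta_l / sigma_g^2. Reference variances
always come from the external LD panel, never from the GWAS itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypePanel, WeightModel

logger = logging.getLogger(__name__)

#: genes with predicted-expression variance below this are dropped
PRED_VAR_EPS = 1e-8


@dataclass
class GrexMatrix:
    samples: np.ndarray
    genes: list
    values: np.ndarray
    tissue: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("GReX matrix shape mismatch")

    def gene_values(self, gene) -> np.ndarray:
        return self.values[:, self.genes.index(gene)]


def predict_grex(panel: GenotypePanel, model: WeightModel) -> GrexMatrix:
    """Predict expression for every gene of a weight model.

    Dosages are counted on the model's effect allele: when the model's
    effect allele is the panel ref, the contribution uses 2 - X. Weight
    rows whose alleles match neither panel orientation, and genes left with
    no scored variant, are dropped and reported.
    """
    vindex = panel.variant_index()
    X = panel.dosages
    col_mean = np.nanmean(X, axis=0) if np.isnan(X).any() else None
    genes, cols, dropped = [], [], []
    pv = panel.variants.set_index("id")
    for gene, sub in model.entries.groupby("gene", sort=True):
        t = np.zeros(panel.n_samples)
        used = 0
        for _, row in sub.iterrows():
            if row["variant_id"] not in vindex:
                continue
            j = vindex.get_loc(row["variant_id"])
            meta = pv.loc[row["variant_id"]]
            x = X[:, j]
            if col_mean is not None and np.isnan(x).any():
                x = np.where(np.isnan(x), col_mean[j], x)
            if row["ea"] == meta["alt"] and row["oa"] == meta["ref"]:
                t = t + row["weight"] * x
            elif row["ea"] == meta["ref"] and row["oa"] == meta["alt"]:
                t = t + row["weight"] * (2.0 - x)
            else:
                continue
            used += 1
        if used == 0:
            dropped.append(gene)
            continue
        genes.append(gene)
        cols.append(t)
    if dropped:
        logger.info("predict_grex(%s): dropped %d genes with no scored "
                    "variant", model.tissue, len(dropped))
    values = np.column_stack(cols) if cols else np.empty((panel.n_samples, 0))
    grex = GrexMatrix(panel.samples, genes, values, model.tissue)
    grex.dropped_genes = dropped
    return grex


def spredixcan(stats_df: pd.DataFrame, model: WeightModel, ld) -> pd.DataFrame:
    """Summary-level gene association for every gene of a weight model.

    ``stats_df`` must already be harmonized to the reference orientation
    (the same orientation the weight model uses). ``ld`` is an
    LdBlockMatrix or block provider with a ``sub(ids)`` method covering the
    model's variants. Returns a tidy table (gene, tissue, zscore, effect,
    pvalue, n_snps_used, pred_var); genes with no variant in the GWAS or
    with degenerate predicted-expression variance are skipped and counted.
    """
    sidx = stats_df.set_index("id")
    skipped_missing = 0
    skipped_degenerate = 0
    rows = []
    for gene, sub in model.entries.groupby("gene", sort=True):
        present = sub["variant_id"].isin(sidx.index)
        sub = sub.loc[present]
        if len(sub) == 0:
            skipped_missing += 1
            continue
        ids = sub["variant_id"].to_numpy()
        try:
            ld_sub = ld.sub(ids)
        except KeyError:
            skipped_missing += 1
            continue
        w = sub.set_index("variant_id").loc[ld_sub.ids, "weight"].to_numpy(float)
        sigma_l = ld_sub.sd
        Sigma = ld_sub.covariance()
        pred_var = float(w @ Sigma @ w)
        if pred_var <= PRED_VAR_EPS:
            skipped_degenerate += 1
            continue
        sigma_g = np.sqrt(pred_var)
        srows = sidx.loc[ld_sub.ids]
        z_l = srows["z"].to_numpy(float)
        beta_l = srows["beta"].to_numpy(float)
        z_g = float(np.sum(w * (sigma_l / sigma_g) * z_l))
        beta_g = float(np.sum(w * sigma_l ** 2 * beta_l) / pred_var)
        rows.append({
            "gene": gene, "tissue": model.tissue, "zscore": z_g,
            "effect": beta_g,
            "pvalue": max(2 * stats.norm.sf(abs(z_g)), 1e-300),
            "n_snps_used": int(len(sub)), "pred_var": pred_var,
        })
    if skipped_missing or skipped_degenerate:
        logger.info("spredixcan(%s): skipped %d genes with no GWAS variant, "
                    "%d with degenerate variance", model.tissue,
                    skipped_missing, skipped_degenerate)
    out = pd.DataFrame(rows, columns=["gene", "tissue", "zscore", "effect",
                                      "pvalue", "n_snps_used", "pred_var"])
    out.attrs["skipped_missing"] = skipped_missing
    out.attrs["skipped_degenerate"] = skipped_degenerate
    return out


def bonferroni_threshold(assoc_tables: list[pd.DataFrame],
                         alpha: float = 0.05) -> float:
    """Bonferroni threshold across all gene-tissue pairs tested."""
    n_tests = sum(len(t) for t in assoc_tables)
    return alpha / n_tests if n_tests else np.nan
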