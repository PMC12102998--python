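"""LD matrices from a reference panel and greedy P-value clumping."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import BlockDiagonalLd, GenotypePanel, LdBlockMatrix

logger = logging.getLogger(__name__)


class EmptyRegionError(ValueError):
    """A requested LD region contains no polymorphic variant."""


def compute_ld(panel: GenotypePanel, region=None,
               shrinkage: float | None = None) -> LdBlockMatrix:
    """Pearson dosage correlation over a region of the panel.

    ``region`` is an iterable of variant ids (default: all variants).
    Missing dosages are mean-imputed per variant; monomorphic variants are
    excluded and reported in the log. ``shrinkage`` in (0,1) shrinks the
    off-diagonal toward identity (Ledoit-Wolf style flat target) for small
    panels.
    """
    sub = panel if region is None else panel.subset_variants(list(region))
    X = sub.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    sd = X.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise EmptyRegionError("region has no polymorphic variant")
    if (~poly).any():
        logger.info("excluded %d monomorphic variants from LD", int((~poly).sum()))
    X = X[:, poly]
    sd = sd[poly]
    R = np.corrcoef(X.T) if X.shape[1] > 1 else np.ones((1, 1))
    R = np.clip(R, -1.0, 1.0)
    if shrinkage:
        R = (1 - shrinkage) * R
        np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    variants = sub.variants.loc[poly.nonzero()[0]]
    return LdBlockMatrix(
        ids=variants["id"].to_numpy(),
        positions=variants["pos"].to_numpy(float),
        matrix=R,
        frequencies=X.mean(axis=0) / 2.0,
        sd=sd,
    )


def compute_ld_blocks(panel: GenotypePanel,
                      block_col: str = "block") -> BlockDiagonalLd:
    """Block-diagonal LD for a panel whose variants carry a block label."""
    blocks = []
    for _, sub in panel.variants.groupby(block_col, sort=True):
        try:
            blocks.append(compute_ld(panel, region=sub["id"]))
        except EmptyRegionError:
            continue
    return BlockDiagonalLd(blocks)


def clump(stats: pd.DataFrame, panel: GenotypePanel,
          r2_max: float = 0.1, window_kb: float = 250.0) -> pd.DataFrame:
    """Greedy P-value clumping against reference-panel LD.

    Repeatedly takes the smallest-P unclaimed variant as an index and
    removes all unclaimed variants within ``window_kb`` of it whose squared
    correlation with the index exceeds ``r2_max``. Ties in P break by
    (position, id) so the result is independent of input row order.
    Variants absent from the panel are treated as unlinked.
    """
    df = stats.sort_values(["p", "pos", "id"], kind="mergesort").reset_index(drop=True)
    pidx = panel.variant_index()
    in_panel = pidx.get_indexer(df["id"])
    absent = int((in_panel < 0).sum())
    if absent:
        logger.info("clump: %d variants absent from panel treated as unlinked",
                    absent)
    X = panel.dosages
    col_means = np.nanmean(X, axis=0) if np.isnan(X).any() else None

    def dosage(col):
        x = X[:, col]
        if col_means is not None and np.isnan(x).any():
            x = np.where(np.isnan(x), col_means[col], x)
        return x

    window = window_kb * 1_000.0
    pos = df["pos"].to_numpy(float)
    chrom = df["chrom"].to_numpy()
    unclaimed = np.ones(len(df), dtype=bool)
    retained = []
    member_of = np.full(len(df), -1)
    for i in range(len(df)):
        if not unclaimed[i]:
            continue
        unclaimed[i] = False
        retained.append(i)
        if in_panel[i] < 0:
            continue
        near = unclaimed & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        cand = np.nonzero(near)[0]
        if len(cand) == 0:
            continue
        xi = dosage(in_panel[i])
        xi_c = xi - xi.mean()
        denom_i = (xi_c ** 2).sum()
        for j in cand:
            if in_panel[j] < 0:
                continue
            xj = dosage(in_panel[j])
            xj_c = xj - xj.mean()
            denom_j = (xj_c ** 2).sum()
            if denom_i == 0 or denom_j == 0:
                continue
            r2 = (xi_c @ xj_c) ** 2 / (denom_i * denom_j)
            if r2 > r2_max:
                unclaimed[j] = False
                member_of[j] = i
    out = df.iloc[retained].copy().reset_index(drop=True)
    members = df.loc[member_of >= 0, "id"]
    index_ids = df.loc[member_of[member_of >= 0], "id"]
    out.attrs["members"] = pd.DataFrame(
        {"member": members.to_numpy(), "index": index_ids.to_numpy()}
    )
    return out
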