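"""Reading/writing the standard formats, variant QC, allele harmonization
and region-wide summary-statistic imputation against a reference LD panel.

Coordinates are 1-based inclusive as in VCF; joins are by position and
alleles, never by rsID alone. P-values of 0 or 1 are clamped into the open
interval so downstream normal-quantile math is always defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    FormatError,
    GenotypePanel,
    LdBlockMatrix,
    SUMSTATS_COLUMNS,
    SUMSTATS_FILE_HEADER,
    WeightModel,
)

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _finalize_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    clamped = (df["p"] <= 0) | (df["p"] >= 1)
    if clamped.any():
        logger.warning("clamped %d p-values into (0, 1)", int(clamped.sum()))
        df["p"] = df["p"].clip(P_FLOOR, 1 - 1e-16)
    df["z"] = df["beta"] / df["se"]
    return df


def read_sumstats(path) -> pd.DataFrame:
    """Read a tab-separated summary-statistics file.

    Rows with unparseable numeric fields are dropped and counted in the log;
    a missing required column raises :class:`FormatError` naming it.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    inverse = {v: k for k, v in SUMSTATS_FILE_HEADER.items()}
    raw = raw.rename(columns=inverse)
    for col in SUMSTATS_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"summary statistics missing required column "
                              f"{SUMSTATS_FILE_HEADER[col]}")
    numeric = ["pos", "eaf", "beta", "se", "p", "n"]
    for col in numeric:
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    bad = raw[numeric].isna().any(axis=1) | (raw["se"] <= 0)
    if bad.any():
        logger.warning("dropped %d malformed summary-statistic rows", int(bad.sum()))
    df = raw.loc[~bad, SUMSTATS_COLUMNS].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(float)
    for col in ("ea", "oa"):
        df[col] = df[col].str.upper()
    df.attrs["n_dropped"] = int(bad.sum())
    return _finalize_sumstats(df)


def write_sumstats(stats: pd.DataFrame, path) -> None:
    out = stats[SUMSTATS_COLUMNS].rename(columns=SUMSTATS_FILE_HEADER)
    out.to_csv(path, sep="\t", index=False)


def read_weights(path, tissue: str | None = None) -> WeightModel:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "variant_id": str})
    rename = {"effect_allele": "ea", "other_allele": "oa"}
    df = df.rename(columns=rename)
    required = {"gene", "variant_id", "ea", "oa", "weight"}
    if not required.issubset(df.columns):
        raise FormatError(f"weight table missing columns "
                          f"{sorted(required - set(df.columns))}")
    if tissue is None:
        tissue = df["tissue"].iloc[0] if "tissue" in df.columns else "unknown"
    return WeightModel(tissue=tissue, entries=df[list(required)].copy())


def write_weights(model: WeightModel, path) -> None:
    out = model.entries.rename(columns={"ea": "effect_allele", "oa": "other_allele"})
    out.insert(0, "tissue", model.tissue)
    out.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(panel: GenotypePanel, path, write_gt: bool = False) -> None:
    """Write dosages as a sites-by-samples VCF with a DS FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        if write_gt:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.samples)) + "\n")
        fmt = "GT:DS" if write_gt else "DS"
        for j, var in panel.variants.iterrows():
            ds = panel.dosages[:, j]
            fields = []
            for d in ds:
                if np.isnan(d):
                    fields.append("./.:." if write_gt else ".")
                elif write_gt:
                    g = int(round(d))
                    gt = ["0/0", "0/1", "1/1"][min(g, 2)]
                    fields.append(f"{gt}:{d:g}")
                else:
                    fields.append(f"{d:g}")
            fh.write(f"{var['chrom']}\t{var['pos']}\t{var['id']}\t{var['ref']}\t"
                     f"{var['alt']}\t.\t.\t.\t{fmt}\t" + "\t".join(fields) + "\n")


def read_vcf(path) -> GenotypePanel:
    """Read a VCF into a GenotypePanel; DS preferred, GT -> dosage fallback."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is normally present
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        rows.append({"chrom": rec.CHROM, "pos": rec.POS,
                     "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                     "ref": rec.REF, "alt": rec.ALT[0] if rec.ALT else "."})
        ds = None
        try:
            arr = rec.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).reshape(-1)
        except Exception:
            ds = None
        if ds is None:
            gts = np.asarray(rec.genotype.array(), dtype=float)
            alleles = gts[:, :2]
            ds = np.where((alleles < 0).any(axis=1), np.nan, alleles.sum(axis=1))
        ds = np.where(ds < 0, np.nan, ds)
        cols.append(ds)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypePanel(samples, variants, dosages)


def _read_vcf_text(path) -> GenotypePanel:
    samples, rows, cols = None, [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = np.array(parts[9:])
                continue
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            ds = []
            for cell in parts[9:]:
                vals = dict(zip(fmt, cell.split(":")))
                if "DS" in vals and vals["DS"] not in (".", ""):
                    ds.append(float(vals["DS"]))
                elif "GT" in vals and "." not in vals["GT"]:
                    ds.append(float(sum(int(a) for a in vals["GT"].replace("|", "/").split("/"))))
                else:
                    ds.append(np.nan)
            rows.append({"chrom": chrom, "pos": pos, "id": vid, "ref": ref, "alt": alt})
            cols.append(np.array(ds))
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypePanel(samples, variants, dosages)


# ---------------------------------------------------------------------------
# QC and harmonization

def qc_filter(stats: pd.DataFrame, maf_min: float = 0.01) -> pd.DataFrame:
    """Retain common biallelic variants: min(eaf, 1-eaf) strictly above
    ``maf_min`` and single-base ref/alt alleles. Removal counts by reason
    go in ``df.attrs['qc_report']``."""
    maf = np.minimum(stats["eaf"], 1 - stats["eaf"])
    rare = maf <= maf_min
    valid_bases = stats["ea"].isin(list("ACGT")) & stats["oa"].isin(list("ACGT"))
    multi = ~valid_bases
    keep = ~(rare | multi)
    out = stats.loc[keep].reset_index(drop=True)
    out.attrs["qc_report"] = {
        "removed_rare": int((rare & ~multi).sum()),
        "removed_not_biallelic_snp": int(multi.sum()),
        "retained": int(keep.sum()),
    }
    return out


def harmonize(stats: pd.DataFrame, target_alleles: pd.DataFrame,
              keep_ambiguous: bool = False,
              ambiguous_freq_margin: float = 0.1) -> pd.DataFrame:
    """Orient summary statistics to a target's ref/alt alleles.

    ``target_alleles`` needs columns chrom, pos, ref, alt. Matching
    orientation passes through; swapped orientation negates beta/z and
    reflects eaf; irreconcilable allele pairs are dropped. Strand-ambiguous
    (A/T, C/G) variants are dropped unless ``keep_ambiguous``, in which case
    they are oriented by allele frequency when it is decisive
    (|eaf - 0.5| > margin) and dropped otherwise.
    """
    tgt = target_alleles.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])
    merged = stats.merge(
        tgt[["ref", "alt"]], left_on=["chrom", "pos"], right_index=True, how="inner"
    )
    ea, oa = merged["ea"], merged["oa"]
    same = (ea == merged["alt"]) & (oa == merged["ref"])
    swap = (ea == merged["ref"]) & (oa == merged["alt"])
    ambiguous = pd.Series(
        [ (a, b) in AMBIGUOUS_PAIRS for a, b in zip(ea, oa) ], index=merged.index
    )

    out = merged.copy()
    if keep_ambiguous:
        decisive = ambiguous & ((out["eaf"] - 0.5).abs() > ambiguous_freq_margin)
        drop_amb = ambiguous & ~decisive
    else:
        drop_amb = ambiguous
    keep = (same | swap) & ~drop_amb
    out = out.loc[keep].copy()
    flip = swap.loc[keep]
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "eaf"] = 1 - out.loc[flip, "eaf"]
    out.loc[flip, ["ea", "oa"]] = out.loc[flip, ["oa", "ea"]].to_numpy()
    out["z"] = out["beta"] / out["se"]
    dropped = len(merged) - len(out)
    if dropped:
        logger.info("harmonize dropped %d variants (%d ambiguous)",
                    dropped, int(drop_amb.sum()))
    out = out.drop(columns=["ref", "alt"]).reset_index(drop=True)
    out.attrs["harmonize_report"] = {
        "flipped": int(flip.sum()), "dropped": dropped,
        "dropped_ambiguous": int(drop_amb.sum()),
    }
    return out


# ---------------------------------------------------------------------------
# summary-statistic imputation

def impute_region_z(stats: pd.DataFrame, ld: LdBlockMatrix,
                    targets=None, lambda_reg: float = 0.1) -> pd.DataFrame:
    """Impute z-scores of unobserved variants in an LD region.

    Uses the Gaussian conditional expectation
    ``z_u = S_uo (S_oo + lambda I)^{-1} z_o`` with S the reference LD
    correlation. The attached ``r2_pred`` column is the corresponding
    prediction r-squared diag(S_uo (S_oo + lambda I)^{-1} S_ou); imputed
    rows are flagged and their beta/se back-filled from z via the reference
    frequency and the median observed sample size.
    """
    ld_index = pd.Index(ld.ids)
    observed_mask = ld_index.isin(stats["id"])
    if targets is None:
        target_ids = ld_index[~observed_mask]
    else:
        target_ids = pd.Index(targets)
    target_ids = target_ids[~target_ids.isin(stats["id"])]
    out = stats.copy()
    if "imputed" not in out.columns:
        out["imputed"] = False
        out["r2_pred"] = 1.0
    if len(target_ids) == 0:
        return out
    obs_ids = ld_index[observed_mask]
    if len(obs_ids) == 0:
        logger.warning("no observed variants in region; %d targets left "
                       "unimputed", len(target_ids))
        return out

    obs_idx = ld_index.get_indexer(obs_ids)
    tgt_idx = ld_index.get_indexer(target_ids)
    S_oo = ld.matrix[np.ix_(obs_idx, obs_idx)] + lambda_reg * np.eye(len(obs_idx))
    S_uo = ld.matrix[np.ix_(tgt_idx, obs_idx)]
    z_o = (stats.set_index("id").loc[obs_ids, "z"]).to_numpy(float)
    W = np.linalg.solve(S_oo, S_uo.T).T          # S_uo @ S_oo^{-1}
    z_u = W @ z_o
    r2 = np.einsum("ij,ij->i", W, ld.matrix[np.ix_(obs_idx, tgt_idx)].T)

    f = ld.frequencies[tgt_idx]
    n_med = float(np.median(stats["n"]))
    se = 1.0 / np.sqrt(np.clip(2 * f * (1 - f), 1e-12, None) * n_med)
    beta = z_u * se
    obs_meta = stats.iloc[0]
    new = pd.DataFrame({
        "chrom": obs_meta["chrom"], "pos": ld.positions[tgt_idx].astype(int),
        "id": np.asarray(target_ids),
        "ea": "?", "oa": "?",
        "eaf": f, "beta": beta, "se": se,
        "p": np.clip(2 * sps.norm.sf(np.abs(z_u)), P_FLOOR, 1.0),
        "n": n_med, "z": z_u,
        "imputed": True, "r2_pred": r2,
    })
    return pd.concat([out, new], ignore_index=True)
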