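"""Shared in-memory containers for the risk-score pipeline.

Tabular data (summary statistics, cohort tables, weight entries) live in
pandas DataFrames with fixed column contracts; genotype dosages and LD
matrices are numpy arrays wrapped in light dataclasses that carry the
sample/variant bookkeeping alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a GWAS summary-statistics table. ``z`` is derived
#: (beta/se) and recomputed on read.
SUMSTATS_COLUMNS = [
    "chrom", "pos", "id", "ea", "oa", "eaf", "beta", "se", "p", "n",
]

#: Column names used in summary-statistics files on disk.
SUMSTATS_FILE_HEADER = {
    "chrom": "CHR", "pos": "POS", "id": "ID", "ea": "EA", "oa": "OA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "p": "P", "n": "N",
}


class FormatError(ValueError):
    """A file or table does not satisfy its column/type contract."""


class ConfigurationError(ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


@dataclass
class GenotypePanel:
    """Dosage matrix plus aligned sample and variant metadata.

    ``dosages`` is n_samples x n_variants with entries in [0, 2] counting
    copies of the alt allele; missing entries are NaN. ``variants`` has
    columns chrom, pos, id, ref, alt (and optionally block).
    """

    samples: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ConfigurationError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ConfigurationError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> pd.Index:
        return pd.Index(self.variants["id"])

    def subset_variants(self, ids) -> "GenotypePanel":
        idx = self.variant_index().get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"variants absent from panel: {missing[:5]}")
        return GenotypePanel(
            self.samples,
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def subset_samples(self, mask) -> "GenotypePanel":
        mask = np.asarray(mask)
        return GenotypePanel(self.samples[mask], self.variants, self.dosages[mask])


@dataclass
class WeightModel:
    """Per-tissue sparse gene -> variant eQTL weight map.

    ``entries`` has columns gene, variant_id, ea, oa, weight; one row per
    (gene, variant) pair, weights finite and nonzero.
    """

    tissue: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "variant_id", "ea", "oa", "weight"}
        if not required.issubset(self.entries.columns):
            raise FormatError(
                f"weight model missing columns {sorted(required - set(self.entries.columns))}"
            )
        w = self.entries["weight"].to_numpy(float)
        if len(w) and (~np.isfinite(w) | (w == 0)).any():
            raise FormatError("weights must be finite and nonzero")
        if self.entries.duplicated(["gene", "variant_id"]).any():
            raise FormatError("duplicate (gene, variant) weight entries")

    @property
    def genes(self) -> list:
        return list(dict.fromkeys(self.entries["gene"]))

    def gene_entries(self, gene) -> pd.DataFrame:
        return self.entries[self.entries["gene"] == gene]


@dataclass
class LdBlockMatrix:
    """Correlation matrix of a variant region, with frequencies and SDs."""

    ids: np.ndarray
    positions: np.ndarray
    matrix: np.ndarray
    frequencies: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        m = len(self.ids)
        if self.matrix.shape != (m, m):
            raise ConfigurationError("LD matrix shape mismatch")
        if m and np.abs(self.matrix - self.matrix.T).max() > 1e-12:
            raise ConfigurationError("LD matrix not symmetric")
        if m and np.abs(np.diag(self.matrix) - 1.0).max() > 1e-9:
            raise ConfigurationError("LD matrix diagonal must be 1")
        if (self.sd <= 0).any():
            raise ConfigurationError("variant SDs must be positive")

    def sub(self, ids) -> "LdBlockMatrix":
        idx = pd.Index(self.ids).get_indexer(ids)
        if (idx < 0).any():
            raise KeyError("requested variants absent from LD matrix")
        return LdBlockMatrix(
            self.ids[idx], self.positions[idx],
            self.matrix[np.ix_(idx, idx)],
            self.frequencies[idx], self.sd[idx],
        )

    def covariance(self) -> np.ndarray:
        return self.matrix * np.outer(self.sd, self.sd)


class BlockDiagonalLd:
    """LD for a whole panel stored block-by-block.

    Cross-block correlations are treated as exactly zero, matching the
    generator's independent-block structure. ``sub`` assembles a dense
    block-diagonal submatrix for an arbitrary variant subset.
    """

    def __init__(self, blocks: list[LdBlockMatrix]):
        self.blocks = blocks
        self._lookup = {}
        for b_i, blk in enumerate(blocks):
            for j, vid in enumerate(blk.ids):
                self._lookup[vid] = (b_i, j)

    @property
    def ids(self) -> np.ndarray:
        return np.concatenate([b.ids for b in self.blocks])

    def sub(self, ids) -> LdBlockMatrix:
        ids = list(ids)
        locs = []
        for vid in ids:
            if vid not in self._lookup:
                raise KeyError(f"variant {vid} absent from LD blocks")
            locs.append(self._lookup[vid])
        m = len(ids)
        mat = np.zeros((m, m))
        pos = np.empty(m)
        freq = np.empty(m)
        sd = np.empty(m)
        for a in range(m):
            ba, ja = locs[a]
            blk = self.blocks[ba]
            pos[a] = blk.positions[ja]
            freq[a] = blk.frequencies[ja]
            sd[a] = blk.sd[ja]
            for b in range(a, m):
                bb, jb = locs[b]
                if bb == ba:
                    mat[a, b] = mat[b, a] = blk.matrix[ja, jb]
        np.fill_diagonal(mat, 1.0)
        return LdBlockMatrix(np.asarray(ids, dtype=object), pos, mat, freq, sd)


@dataclass
class ScoreVector:
    """Per-individual risk score with provenance.

    ``standardized`` is (raw - mu)/sigma where (mu, sigma) come from the
    declared standardization reference (the training set by default) and
    transport unchanged to any other sample set.
    """

    samples: np.ndarray
    raw: np.ndarray
    score_type: str = "PRS"
    threshold: float | None = None
    n_features: int = 0
    tissue: str | None = None
    standardized: np.ndarray | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.samples) != len(self.raw):
            raise ConfigurationError("score length does not match samples")

    @property
    def values(self) -> np.ndarray:
        """Standardized values when available, raw otherwise."""
        return self.raw if self.standardized is None else self.standardized

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample": self.samples, "raw": self.raw})
        if self.standardized is not None:
            out["standardized"] = self.standardized
        return out


@dataclass
class GroundTruth:
    """Generative record used by parameter-recovery tests."""

    true_gene_effects: dict = field(default_factory=dict)
    true_variant_effects: dict = field(default_factory=dict)
    true_weights: dict = field(default_factory=dict)
    liability: np.ndarray | None = None
    threshold: float | None = None
    causal_tissues: list = field(default_factory=list)
    components: dict = field(default_factory=dict)


#: Covariate column names used throughout the risk models.
PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]
DEFAULT_COVARIATES = ["age", "sex"] + PC_COLUMNS
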