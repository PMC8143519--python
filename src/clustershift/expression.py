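"""Count-matrix data model, TMM normalization and the log2-TPM expression matrix.

Counts arrive as a gene × sample table of non-negative integers, optionally with
per-gene effective lengths.  Between-sample normalization follows the trimmed
mean of M-values (TMM) scheme: for every sample a scaling factor is estimated
from doubly-trimmed, precision-weighted log expression ratios against a
reference sample, and the factor multiplies the library size inside the TPM
denominator.  Expression used downstream is ``log2(TPM' + pseudocount)``.

Two QC helpers mirror the usual first-look figures: PCA of sample profiles on
gene-centred expression, and a gene-wise z-score matrix with hierarchical
row/column orders for heatmap display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

TISSUES = ("epidermis", "soft_tissue")
TREATMENTS = ("control", "inhibitor")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene × sample matrix of raw counts with optional effective lengths (nt)."""

    counts: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = sorted(set(c.index[c.index.duplicated()]))
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        if c.columns.duplicated().any():
            dups = sorted(set(c.columns[c.columns.duplicated()]))
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at gene {c.index[bad[0]]!r}, "
                    f"sample {c.columns[bad[1]]!r}"
                )
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {c.index[bad[0]]!r}, "
                f"sample {c.columns[bad[1]]!r}"
            )
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = sorted(self.counts.index[self.lengths.isna()])
                raise ValidationError(f"genes missing effective lengths: {missing[:10]}")
            if (self.lengths <= 0).any():
                raise ValidationError("effective lengths must be > 0")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class SampleTable:
    """Sample metadata: tissue, timepoint (dpa), treatment and replicate."""

    table: pd.DataFrame

    REQUIRED = ("tissue", "timepoint_dpa", "treatment", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        if t.index.duplicated().any():
            raise ValidationError("duplicate sample identifiers in sample table")
        key = t[list(self.REQUIRED)].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValidationError("duplicate (tissue, timepoint, treatment, replicate) tuples")
        t0 = min(t["timepoint_dpa"])
        bad = t[(t["timepoint_dpa"] == t0) & (t["treatment"] != "control")]
        if len(bad):
            raise ValidationError(
                f"baseline timepoint {t0} must carry treatment 'control' only"
            )

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def subset(self, tissue: str) -> "SampleTable":
        sub = self.table[self.table["tissue"] == tissue]
        if sub.empty:
            raise ValidationError(f"no samples for tissue {tissue!r}")
        return SampleTable(sub.copy())

    def timepoints(self) -> list:
        return sorted(self.table["timepoint_dpa"].unique())


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors, rescaled to geometric mean 1."""

    factors: pd.Series
    reference: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("TMM factors must be positive")


@dataclass
class ExpressionMatrix:
    """log2-scale normalized expression with a provenance record."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values")
        if not self.provenance:
            raise ValidationError("expression matrix requires a provenance record")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(counts_path: str | Path, lengths_path: str | Path | None = None) -> CountMatrix:
    """Read a counts TSV (gene rows, sample columns) and optional lengths TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(df.columns):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                i = int(np.argmax(vals.isna().to_numpy()))
                raise ValidationError(
                    f"unparseable count at gene {df.index[i]!r}, sample {col!r}"
                )
        df = df.apply(pd.to_numeric)
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0, comment="#")
        lengths = lt.iloc[:, 0].astype(float)
    return CountMatrix(df, lengths)


def write_counts(cm: CountMatrix, counts_path: str | Path,
                 lengths_path: str | Path | None = None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    if lengths_path is not None and cm.lengths is not None:
        cm.lengths.rename("length").to_csv(lengths_path, sep="\t", index_label="gene")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return SampleTable(df)


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.table.to_csv(path, sep="\t", index_label="sample")


def filter_expressed(cm: CountMatrix, min_count: int = 1, min_samples: int = 1) -> CountMatrix:
    """Keep genes with ``count >= min_count`` in at least ``min_samples`` samples."""
    keep = (cm.counts >= min_count).sum(axis=1) >= min_samples
    lengths = cm.lengths[keep] if cm.lengths is not None else None
    return CountMatrix(cm.counts.loc[keep], lengths)


# ---------------------------------------------------------------------------
# TPM and TMM
# ---------------------------------------------------------------------------

def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates rescaled to 1e6 per sample.

    All-zero samples yield an all-zero TPM column.
    """
    if cm.lengths is None:
        raise ValidationError("TPM requires gene effective lengths")
    rate = cm.counts.div(cm.lengths, axis=0)
    denom = rate.sum(axis=0)
    safe = denom.replace(0, np.nan)
    tpm = rate.div(safe, axis=1) * 1e6
    return tpm.fillna(0.0)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """TMM factor of one library against the reference (doubly trimmed,
    precision-weighted mean of M-values)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        logger.warning("TMM: no co-expressed genes with reference; factor set to 1")
        return 1.0
    o = obs[pos].astype(float)
    r = ref[pos].astype(float)
    p_o = o / lib_obs
    p_r = r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) variance of M as the precision weight
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    wsum = np.sum(1.0 / w[keep])
    f = np.sum(m[keep] / w[keep]) / wsum
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, reference: str | None = None) -> NormalizationFactors:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    The reference (when not given) is the sample whose upper-quartile
    count proportion is closest to the mean upper quartile.
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        empty = sorted(counts.columns[lib == 0])
        raise ValidationError(f"samples with zero total counts: {empty}")
    if reference is None:
        q75 = counts.apply(lambda col: np.quantile(col.to_numpy(), 0.75)) / lib
        reference = str(q75.index[np.argmin(np.abs(q75 - q75.mean()))])
    elif reference not in counts.columns:
        raise ValidationError(f"reference sample {reference!r} not in matrix")
    ref = counts[reference].to_numpy()
    lib_ref = float(lib[reference])
    fac = {}
    for s in counts.columns:
        if s == reference:
            fac[s] = 1.0
        else:
            fac[s] = _tmm_pair(counts[s].to_numpy(), ref, float(lib[s]), lib_ref)
    factors = pd.Series(fac, name="tmm_factor")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(factors, reference)


def normalize(cm: CountMatrix, factors: NormalizationFactors,
              pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM' + pseudocount), with the TMM factor scaling each sample's
    effective library size inside the TPM denominator."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    missing = [s for s in cm.samples if s not in factors.factors.index]
    if missing:
        raise ValidationError(f"missing TMM factors for samples: {missing}")
    if cm.lengths is None:
        raise ValidationError("normalization requires gene effective lengths")
    rate = cm.counts.div(cm.lengths, axis=0)
    denom = rate.sum(axis=0) * factors.factors.reindex(cm.samples)
    safe = denom.replace(0, np.nan)
    tpm = (rate.div(safe, axis=1) * 1e6).fillna(0.0)
    values = np.log2(tpm + pseudocount)
    prov = {
        "unit": "log2(TPM'+pseudocount)",
        "pseudocount": pseudocount,
        "tmm_reference": factors.reference,
        "tmm_factors": factors.factors.to_dict(),
    }
    return ExpressionMatrix(values, prov)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_pca(expr: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on gene-centred expression (no gene scaling).

    Returns per-sample coordinates and explained-variance percentages,
    non-increasing and summing to <= 100.
    """
    x = expr.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValidationError("PCA requires at least 2 samples")
    centred = (x - x.mean(axis=1, keepdims=True)).T  # samples × genes
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        logger.warning("qc_pca: zero total variance; identical sample profiles")
        frac = np.zeros_like(var)
    else:
        frac = var / total
    k = min(x.shape[1], len(s))
    coords = pd.DataFrame(
        (u * s)[:, :k], index=expr.samples,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    return coords, 100.0 * frac[:k]


def zscore_rows(values: pd.DataFrame, eps: float = 1e-12) -> tuple[pd.DataFrame, pd.Index]:
    """Row-wise z-scores (sample sd, ddof=1); zero-variance rows become all-zero
    and are returned as flags."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] < eps
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=values.index, columns=values.columns), values.index[flat]


def qc_heatmap_matrix(expr: ExpressionMatrix) -> dict:
    """Gene-wise z-score matrix plus average-linkage Euclidean dendrogram leaf
    orders for rows (genes) and columns (samples)."""
    if expr.values.shape[1] < 2:
        raise ValidationError("heatmap QC requires at least 2 samples")
    z, flat = zscore_rows(expr.values)
    if len(flat):
        logger.info("qc_heatmap_matrix: %d zero-variance genes set to 0", len(flat))
    zarr = z.to_numpy()
    row_order = leaves_list(linkage(zarr, method="average", metric="euclidean")) \
        if zarr.shape[0] > 1 else np.array([0])
    col_order = leaves_list(linkage(zarr.T, method="average", metric="euclidean")) \
        if zarr.shape[1] > 1 else np.array([0])
    return {
        "zscores": z,
        "zero_variance_genes": list(flat),
        "row_order": row_order,
        "col_order": col_order,
    }
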