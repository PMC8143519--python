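"""Signature-based cell-type abundance scores.

The relative abundance of a cell type in a bulk sample is proxied by the
arithmetic mean of its signature genes' normalized expression; a z-scored
variant standardizes each cell type across samples for cross-type display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .expression import ExpressionMatrix, ValidationError, zscore_rows

logger = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    """Cell type → marker gene list."""

    signatures: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)


@dataclass
class AbundanceTable:
    values: pd.DataFrame          # cell type × sample
    scale: str                    # "raw_mean" or "zscore_by_type"
    flags: list = field(default_factory=list)


def estimate_abundance(expr: ExpressionMatrix, signatures: SignatureSet,
                       linear_scale: bool = False) -> AbundanceTable:
    """Mean signature-gene expression per (cell type, sample).

    Genes absent from the matrix are logged and skipped, never imputed; a
    cell type with no present genes is dropped with a warning.  With
    ``linear_scale`` the mean is taken on 2^expression − pseudocount-free
    linear values instead of the log2 matrix.
    """
    vals = expr.values
    if linear_scale:
        vals = 2.0 ** vals
    rows = {}
    for ct, genes in signatures.signatures.items():
        present = [g for g in genes if g in vals.index]
        missing = len(genes) - len(present)
        if missing:
            logger.info("signature %r: %d/%d genes absent from the matrix",
                        ct, missing, len(genes))
        if not present:
            logger.warning("signature %r has no measured genes; dropped", ct)
            continue
        rows[ct] = vals.loc[present].mean(axis=0)
    if not rows:
        raise ValidationError("no signature has measured genes")
    return AbundanceTable(pd.DataFrame(rows).T, scale="raw_mean")


def zscore_abundance(table: AbundanceTable) -> AbundanceTable:
    """Standardize each cell-type row across samples (constant rows → zeros,
    flagged); idempotent on already-standardized rows."""
    if table.values.shape[1] < 2:
        raise ValidationError("z-scoring requires >= 2 samples")
    z, flat = zscore_rows(table.values)
    return AbundanceTable(z, scale="zscore_by_type", flags=list(flat))
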