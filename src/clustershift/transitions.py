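"""Control → inhibitor cluster-transition matrix and transition gene sets.

Both arms of every gene are clustered jointly in one fuzzy c-means fit, so the
hard assignments live in a shared centroid space; the transition matrix counts,
for genes in each control cluster (row), how many land in each cluster under
the inhibitor (column).  Row-normalized proportions are the headline analytic
object: off-diagonal mass marks treatment-altered temporal programs, and the
per-cell gene lists feed enrichment analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .expression import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame        # control cluster × inhibitor cluster, ints
    proportions: pd.DataFrame   # row-normalized; empty rows all-zero
    empty_rows: list = field(default_factory=list)


def _paired_assignments(model: ClusterModel,
                        control: str = "control",
                        treated: str = "inhibitor") -> pd.DataFrame:
    a = model.assignments
    if not isinstance(a.index, pd.MultiIndex):
        raise ValidationError("cluster model rows must be (gene, treatment) pairs")
    df = a.unstack("treatment")
    for arm in (control, treated):
        if arm not in df.columns:
            raise ValidationError(f"no {arm!r} rows in cluster model")
    incomplete = df.index[df[[control, treated]].isna().any(axis=1)]
    if len(incomplete):
        logger.info("excluding %d genes with a single treatment row", len(incomplete))
    return df.loc[df[[control, treated]].notna().all(axis=1), [control, treated]].astype(int)


def compute_transition_matrix(model: ClusterModel,
                              control: str = "control",
                              treated: str = "inhibitor") -> TransitionMatrix:
    """counts[i, j] = number of genes assigned to cluster i under control and
    cluster j under the inhibitor; proportions are row-normalized."""
    pairs = _paired_assignments(model, control, treated)
    labels = list(range(1, model.c + 1))
    counts = pd.crosstab(pairs[control], pairs[treated]) \
        .reindex(index=labels, columns=labels, fill_value=0)
    counts.index.name = "control_cluster"
    counts.columns.name = "inhibitor_cluster"
    row_sums = counts.sum(axis=1)
    empty = [int(i) for i in row_sums.index[row_sums == 0]]
    props = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return TransitionMatrix(counts=counts.astype(int), proportions=props, empty_rows=empty)


def extract_transition_genes(model: ClusterModel, from_cluster: int, to_cluster: int,
                             control: str = "control",
                             treated: str = "inhibitor") -> list[str]:
    """Sorted genes assigned to ``from_cluster`` under control and
    ``to_cluster`` under the inhibitor (equal indices mean no transition)."""
    for idx in (from_cluster, to_cluster):
        if not 1 <= idx <= model.c:
            raise ValidationError(f"cluster index {idx} out of range 1..{model.c}")
    pairs = _paired_assignments(model, control, treated)
    hit = pairs[(pairs[control] == from_cluster) & (pairs[treated] == to_cluster)]
    return sorted(hit.index)
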