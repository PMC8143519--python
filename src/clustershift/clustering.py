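"""Merged-condition temporal profiles and fuzzy c-means clustering.

For every dynamic gene a 3-point temporal profile (replicate means at 0, 3, 8
dpa, z-scored per row) is built separately for the control and inhibitor arms
— the shared homeostatic 0-dpa mean is reused by both — and the two rows are
stacked in ONE matrix.  A single fuzzy c-means fit over the merged matrix puts
both arms in the same centroid space, which is what makes cluster-transition
counting meaningful downstream.

The cluster number is chosen by the minimum-centroid-distance criterion:
fuzzy c-means is run for c in a scan range and the smallest pairwise centroid
distance d_min(c) is recorded; once c exceeds the true structure, surplus
centroids collapse onto each other and d_min drops sharply.  The chosen c is
the largest one with d_min above a threshold θ (default 0.1 in z-score units).

The fuzzifier default follows the dimension/size-based estimate

    m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .expression import ExpressionMatrix, SampleTable, ValidationError, zscore_rows
from .de import group_label

logger = logging.getLogger(__name__)


@dataclass
class TemporalProfileMatrix:
    """Rows (gene, treatment) × timepoints of z-scored mean log2 expression."""

    values: pd.DataFrame          # MultiIndex (gene, treatment) × timepoints
    dropped: list = field(default_factory=list)

    @property
    def genes(self) -> list:
        return sorted({g for g, _ in self.values.index})


@dataclass
class ClusterModel:
    c: int
    m: float
    centroids: pd.DataFrame       # cluster × timepoints
    memberships: pd.DataFrame     # rows × cluster
    assignments: pd.Series        # row -> cluster index (argmax membership)
    objective: float
    iterations: int
    seed: int


@dataclass
class ClusterNumberScan:
    table: pd.DataFrame           # columns: c, d_min
    chosen_c: int
    theta: float


def build_profiles(expr: ExpressionMatrix, samples: SampleTable,
                   genes: list[str]) -> TemporalProfileMatrix:
    """Per-gene, per-arm replicate-mean profiles over timepoints, z-scored.

    The baseline timepoint has control samples only; its mean is reused for
    the inhibitor arm.  Rows with sd < 1e-12 are dropped and logged.
    """
    t = samples.table
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing[:10]}")
    tps = sorted(t["timepoint_dpa"].unique())
    t0 = tps[0]
    treatments = sorted(t.loc[t["timepoint_dpa"] != t0, "treatment"].unique())
    # group means per (timepoint, treatment)
    group_cols: dict[tuple, list] = {}
    for s, row in t.iterrows():
        group_cols.setdefault((row["timepoint_dpa"], row["treatment"]), []).append(s)
    sub = expr.values.loc[genes]
    means = {}
    base_mean = sub[group_cols[(t0, "control")]].mean(axis=1)
    for treat in treatments:
        cols = {t0: base_mean}
        for tp in tps[1:]:
            key = (tp, treat)
            if key not in group_cols:
                raise ValidationError(f"no samples for timepoint {tp}, treatment {treat}")
            cols[tp] = sub[group_cols[key]].mean(axis=1)
        means[treat] = pd.DataFrame(cols)
    rows = []
    index = []
    for g in genes:
        for treat in treatments:
            rows.append(means[treat].loc[g].to_numpy(dtype=float))
            index.append((g, treat))
    mat = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["gene", "treatment"]),
                       columns=tps)
    z, flat = zscore_rows(mat)
    dropped_genes = sorted({g for g, _ in flat})
    if dropped_genes:
        logger.info("build_profiles: dropped %d genes with a flat profile row",
                    len(dropped_genes))
    keep = [idx for idx in z.index if idx[0] not in set(dropped_genes)]
    return TemporalProfileMatrix(z.loc[keep], dropped=dropped_genes)


def estimate_fuzzifier(profiles: TemporalProfileMatrix | pd.DataFrame) -> float:
    """Size/dimension-based fuzzifier estimate; always > 1."""
    vals = profiles.values if isinstance(profiles, TemporalProfileMatrix) else profiles
    n, d = vals.shape
    if n < 10:
        raise ValidationError("fuzzifier estimate requires >= 10 rows")
    if d < 2:
        raise ValidationError("fuzzifier estimate requires >= 2 columns")
    m = 1.0 + (1418.0 / n + 22.05) * d**-2 \
        + (12.33 / n + 0.243) * d**(-0.0406 * np.log(n) - 0.1134)
    return float(m)


def _memberships(x: np.ndarray, v: np.ndarray, m: float) -> np.ndarray:
    d2 = cdist(x, v, "sqeuclidean")
    zero = d2 < 1e-300
    u = np.zeros_like(d2)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        # coincident with >= 1 centroid: full membership split among them
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        inv = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _kmeanspp_init(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """Spread initial centroids over the data: each next centroid is drawn with
    probability proportional to the squared distance from the chosen ones."""
    n = x.shape[0]
    centroids = [x[rng.integers(n)]]
    d2 = np.sum((x - centroids[0]) ** 2, axis=1)
    for _ in range(1, c):
        total = d2.sum()
        if total <= 0:
            centroids.append(x[rng.integers(n)])
            continue
        pick = rng.choice(n, p=d2 / total)
        centroids.append(x[pick])
        d2 = np.minimum(d2, np.sum((x - centroids[-1]) ** 2, axis=1))
    return np.array(centroids)


def _lloyd_polish(x: np.ndarray, v: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """A few hard-assignment (k-means) iterations to settle the initial
    centroids on the data's coarse structure before the fuzzy alternation;
    empty clusters keep their previous position."""
    for _ in range(n_iter):
        lab = cdist(x, v, "sqeuclidean").argmin(axis=1)
        new_v = v.copy()
        for i in range(v.shape[0]):
            mask = lab == i
            if mask.any():
                new_v[i] = x[mask].mean(axis=0)
        if np.allclose(new_v, v):
            break
        v = new_v
    return v


def _objective(x: np.ndarray, v: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = cdist(x, v, "sqeuclidean")
    return float(np.sum(u**m * d2))


def fuzzy_cmeans(profiles: TemporalProfileMatrix | pd.DataFrame, c: int, m: float,
                 seed: int = 0, restarts: int = 3, tol: float = 1e-6,
                 max_iter: int = 200) -> ClusterModel:
    """Fuzzy c-means with seeded k-means++-style initializations.

    Alternates the centroid update v_i = Σ u^m x / Σ u^m and the membership
    update u_ij ∝ d_ij^(−2/(m−1)) until max |ΔU| < tol; the best of
    ``restarts`` initializations by the objective J = Σ u^m d² is kept.
    Initial centroids are chosen over identifier-sorted rows, so results do
    not depend on row order.
    Cluster labels are canonicalized by lexicographic centroid order, so the
    numbering is reproducible and row-permutation invariant.
    """
    vals = profiles.values if isinstance(profiles, TemporalProfileMatrix) else profiles
    x = vals.to_numpy(dtype=float)
    n, d = x.shape
    if c < 2 or m <= 1:
        raise ValidationError("need c >= 2 and m > 1")
    if c > n:
        raise ValidationError(f"c = {c} exceeds {n} rows")
    rng = np.random.default_rng(seed)
    # row order must not matter: k-means++-style seeding runs on rows sorted
    # by identifier, so only the seed and the row *values* decide the init
    sort_idx = np.argsort([str(i) for i in vals.index])
    x_sorted = x[sort_idx]
    best = None
    for _ in range(max(restarts, 1)):
        v = _kmeanspp_init(x_sorted, c, rng)
        v = _lloyd_polish(x, v)
        u = _memberships(x, v, m)
        n_iter = 0
        prev_j = np.inf
        for n_iter in range(1, max_iter + 1):
            um = u**m
            v = (um.T @ x) / um.sum(axis=0)[:, None]
            u_new = _memberships(x, v, m)
            j = _objective(x, v, u_new, m)
            if j > prev_j + 1e-9:
                logger.warning("fuzzy c-means objective increased at iter %d", n_iter)
            prev_j = j
            delta = np.max(np.abs(u_new - u))
            u = u_new
            if delta < tol:
                break
        if best is None or prev_j < best[0]:
            best = (prev_j, v.copy(), u.copy(), n_iter)
    j, v, u, n_iter = best
    # canonical label order: lexicographic over timepoint values
    order = np.lexsort(tuple(v[:, k] for k in range(d - 1, -1, -1)))
    v = v[order]
    u = u[:, order]
    assignments = u.argmax(axis=1)  # argmax breaks ties toward the lowest index
    return ClusterModel(
        c=c, m=float(m),
        centroids=pd.DataFrame(v, index=range(1, c + 1), columns=vals.columns),
        memberships=pd.DataFrame(u, index=vals.index, columns=range(1, c + 1)),
        assignments=pd.Series(assignments + 1, index=vals.index, name="cluster"),
        objective=float(j), iterations=int(n_iter), seed=seed,
    )


def min_centroid_distance(model: ClusterModel) -> float:
    return float(pdist(model.centroids.to_numpy()).min())


def select_cluster_number(profiles: TemporalProfileMatrix | pd.DataFrame, m: float,
                          c_range: tuple[int, int] = (4, 27), theta: float = 0.1,
                          seed: int = 0, restarts: int = 1) -> ClusterNumberScan:
    """Scan c over ``c_range`` and choose the largest c whose minimum pairwise
    centroid distance stays above θ; fall back to the smallest scanned c with
    a warning when no c qualifies."""
    vals = profiles.values if isinstance(profiles, TemporalProfileMatrix) else profiles
    lo, hi = int(c_range[0]), int(c_range[1])
    if lo < 2 or hi >= len(vals):
        raise ValidationError(f"scan range {c_range} must lie within [2, rows-1]")
    records = []
    for c in range(lo, hi + 1):
        model = fuzzy_cmeans(profiles, c, m, seed=seed, restarts=restarts)
        records.append((c, min_centroid_distance(model)))
    table = pd.DataFrame(records, columns=["c", "d_min"])
    ok = table[table["d_min"] > theta]
    if ok.empty:
        logger.warning("no cluster count reaches d_min > %.3g; falling back to c=%d",
                       theta, lo)
        chosen = lo
    else:
        chosen = int(ok["c"].max())
    return ClusterNumberScan(table=table, chosen_c=chosen, theta=theta)
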