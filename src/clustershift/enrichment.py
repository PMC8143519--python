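"""Preranked GSEA, hypergeometric over-representation and enrichment maps.

Genes are ranked by the signed log p-value of one differential-expression
contrast, r_g = sign(log2FC) · (−log10 p): strongly up-regulated genes at the
top, strongly down-regulated at the bottom.  The enrichment score is the
weighted Kolmogorov–Smirnov running-sum statistic; significance comes from
gene-label permutations (random same-size sets), which is the appropriate
null when per-group replication is too small for phenotype permutation.
Over-representation uses the upper-tail hypergeometric with BH adjustment.

Significant sets can be assembled into an enrichment-map graph whose edges
join sets with Jaccard (or overlap-coefficient) similarity above a cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a measured-gene universe on demand."""

    sets: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes within set {name!r}")

    def restrict(self, universe) -> "GeneSetCollection":
        """Drop genes outside the universe; sets emptied by restriction are
        removed (and logged)."""
        uni = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            inside = [g for g in genes if g in uni]
            if inside:
                kept[name] = inside
            else:
                logger.info("set %r empty after universe restriction; dropped", name)
        prov = dict(self.provenance)
        prov["restricted_to_universe"] = len(uni)
        return GeneSetCollection(kept, prov)

    def __len__(self) -> int:
        return len(self.sets)


def rank_genes(de_slice: pd.DataFrame) -> pd.Series:
    """Signed log-p ranking of one contrast, descending.

    r_g = −log10(p) for fold change > 1 (log2FC > 0) and +log10(p) otherwise.
    Ties are broken by |log2FC| descending, then gene identifier; p = 0 is
    clamped to the smallest positive float with a warning.
    """
    if "p" not in de_slice or "log2FC" not in de_slice:
        raise ValidationError("ranking requires 'p' and 'log2FC' columns")
    if de_slice["log2FC"].isna().any():
        raise ValidationError("missing fold change in DE slice")
    p = de_slice["p"].to_numpy(dtype=float)
    if (p <= 0).any():
        logger.warning("p-values of 0 clamped to the machine minimum")
        p = np.maximum(p, np.finfo(float).tiny)
    lfc = de_slice["log2FC"].to_numpy(dtype=float)
    score = np.where(lfc > 0, -np.log10(p), np.log10(p))
    order = pd.DataFrame({
        "score": score,
        "abs_lfc": np.abs(lfc),
        "gene": de_slice.index,
    }).sort_values(["score", "abs_lfc", "gene"], ascending=[False, False, True])
    return pd.Series(order["score"].to_numpy(), index=pd.Index(order["gene"], name="gene"),
                     name="score")


def gsea_es(ranked: pd.Series, gene_set, weight: float = 1.0):
    """Weighted KS running-sum enrichment score of one set.

    Hits add |r|^weight / N_R, misses subtract 1/(N − N_H); the ES is the
    signed maximum deviation of the running sum from zero.  Returns
    (ES, running-sum curve, leading-edge gene list).
    """
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n = len(genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValidationError("gene set does not intersect the ranked universe")
    w = np.abs(scores[hit]) ** weight
    nr = w.sum()
    steps = np.zeros(n)
    if nr > 0:
        steps[hit] = w / nr
    else:  # all hit scores are zero: fall back to equal hit increments
        steps[hit] = 1.0 / n_hit
    if n_hit < n:
        steps[~hit] = -1.0 / (n - n_hit)
    run = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(run)))
    es = float(run[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[:i_ext + 1], hit[:i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return es, run, leading


def _null_es_for_size(scores: np.ndarray, k: int, n_perm: int,
                      rng: np.random.Generator, weight: float) -> np.ndarray:
    """Vectorized null ES for random sets of size k over the given ranking."""
    n = len(scores)
    absw = np.abs(scores) ** weight
    # sample k distinct positions per permutation
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    idx.sort(axis=1)
    w = absw[idx]
    cum_w = np.cumsum(w, axis=1)
    nr = cum_w[:, -1]
    zero_nr = nr <= 0
    nr[zero_nr] = 1.0
    w_frac = cum_w / nr[:, None]
    if zero_nr.any():
        w_frac[zero_nr] = (np.arange(1, k + 1) / k)[None, :]
    j = np.arange(k)[None, :]
    miss_step = 1.0 / (n - k) if n > k else 0.0
    # running sum just after hit j: j+1 hits and idx_j − j misses processed
    after = w_frac - (idx - j) * miss_step
    # running sum just before hit j: j hits and idx_j − j misses processed
    before = np.concatenate([np.zeros((n_perm, 1)), w_frac[:, :-1]], axis=1) \
        - (idx - j) * miss_step
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


@dataclass
class GSEAResult:
    table: pd.DataFrame           # per set: ES, NES, p, q, size, leading_edge
    n_perm: int
    seed: int


def gsea_preranked(ranked: pd.Series, sets: GeneSetCollection, n_perm: int = 1000,
                   seed: int = 0, weight: float = 1.0) -> GSEAResult:
    """Preranked GSEA with a gene-label permutation null.

    NES = ES / mean |null ES| of matching sign; nominal p uses the same-sign
    null tail with add-one correction; FDR q follows the NES-based tail-ratio
    procedure on the pooled sign-normalized null.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    universe = list(ranked.index)
    restricted = sets.restrict(universe)
    scores = ranked.to_numpy(dtype=float)
    n = len(scores)
    rng = np.random.default_rng(seed)
    sizes = sorted({len(v) for v in restricted.sets.values()})
    null_by_size: dict[int, np.ndarray] = {}
    for k in sizes:
        if k >= n:
            raise ValidationError(f"set of size {k} >= universe size {n}")
        null_by_size[k] = _null_es_for_size(scores, k, n_perm, rng, weight)

    rows = []
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    for name, genes in restricted.sets.items():
        es, _, leading = gsea_es(ranked, genes, weight)
        null = null_by_size[len(genes)]
        pos = null[null > 0]
        neg = null[null < 0]
        if es >= 0:
            denom = pos.mean() if pos.size else np.nan
            pval = (1.0 + np.sum(pos >= es)) / (1.0 + pos.size) if pos.size else 1.0
        else:
            denom = -neg.mean() if neg.size else np.nan
            pval = (1.0 + np.sum(neg <= es)) / (1.0 + neg.size) if neg.size else 1.0
        nes = es / denom if np.isfinite(denom) and denom > 0 else 0.0
        mpos = pos.mean() if pos.size else np.nan
        mneg = -neg.mean() if neg.size else np.nan
        if np.isfinite(mpos) and mpos > 0:
            null_nes_pos.append(pos / mpos)
        if np.isfinite(mneg) and mneg > 0:
            null_nes_neg.append(neg / mneg)
        rows.append({"set": name, "size": len(genes), "ES": es, "NES": nes,
                     "p": pval, "leading_edge": leading})
    table = pd.DataFrame(rows).set_index("set")

    # FDR q: tail-ratio of pooled sign-normalized null NES vs observed NES
    pool_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    pool_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.array([])
    obs = table["NES"].to_numpy()
    q = np.ones(len(table))
    for i, nes in enumerate(obs):
        if nes >= 0:
            null_frac = np.mean(pool_pos >= nes) if pool_pos.size else 1.0
            obs_frac = np.mean(obs[obs >= 0] >= nes) if (obs >= 0).any() else 1.0
        else:
            null_frac = np.mean(pool_neg <= nes) if pool_neg.size else 1.0
            obs_frac = np.mean(obs[obs < 0] <= nes) if (obs < 0).any() else 1.0
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    # enforce monotonicity in |NES| within each sign
    for sign in (1, -1):
        mask = (obs >= 0) if sign == 1 else (obs < 0)
        if mask.any():
            order = np.argsort(-np.abs(obs[mask]))
            qi = q[mask][order]
            qi = np.minimum.accumulate(qi[::-1])[::-1]
            tmp = q[mask]
            tmp[order] = qi
            q[mask] = tmp
    table["q"] = q
    return GSEAResult(table=table, n_perm=n_perm, seed=seed)


def ora_hypergeometric(query, sets: GeneSetCollection, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH adjustment.

    p = P(X >= k) with K set genes in a universe of N and a query of n.
    Query genes outside the universe are dropped and logged.
    """
    uni = set(universe)
    n_universe = len(uni)
    q_in = sorted(set(query) & uni)
    dropped = sorted(set(query) - uni)
    if dropped:
        logger.info("ORA: %d query genes outside the universe dropped", len(dropped))
    if not q_in:
        raise ValidationError("empty query after universe restriction")
    restricted = sets.restrict(universe)
    qset = set(q_in)
    rows = []
    for name, genes in restricted.sets.items():
        kk = len(set(genes) & qset)
        bigk = len(genes)
        p = float(stats.hypergeom.sf(kk - 1, n_universe, bigk, len(q_in)))
        rows.append({"set": name, "overlap": kk, "set_size": bigk,
                     "query_size": len(q_in), "universe_size": n_universe,
                     "p": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values(["p", "set_size"])


def build_enrichment_map(results: pd.DataFrame, sets: GeneSetCollection,
                         universe=None, q_cut: float = 0.05, sim_cut: float = 0.25,
                         metric: str = "jaccard") -> nx.Graph:
    """Graph of significant sets (q < q_cut); undirected edges join pairs with
    similarity >= sim_cut (Jaccard or overlap coefficient) on the
    universe-restricted sets."""
    if "q" not in results:
        raise ValidationError("results must carry a 'q' column")
    sig = results[results["q"] < q_cut]
    coll = sets.restrict(universe) if universe is not None else sets
    g = nx.Graph()
    members = {}
    for name in sig.index:
        if name not in coll.sets:
            continue
        members[name] = set(coll.sets[name])
        attrs = {"q": float(sig.loc[name, "q"]), "size": len(members[name])}
        if "NES" in sig.columns:
            attrs["NES"] = float(sig.loc[name, "NES"])
        g.add_node(name, **attrs)
    names = list(members)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(members[a] & members[b])
            if metric == "jaccard":
                denom = len(members[a] | members[b])
            elif metric == "overlap":
                denom = min(len(members[a]), len(members[b]))
            else:
                raise ValidationError(f"unknown similarity metric {metric!r}")
            sim = inter / denom if denom else 0.0
            if sim >= sim_cut:
                g.add_edge(a, b, similarity=sim)
    return g
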