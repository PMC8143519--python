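"""Ranking, GSEA running sum, ORA exactness and the enrichment map."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clustershift.enrichment import (GeneSetCollection, ValidationError,
                                     build_enrichment_map, gsea_es,
                                     gsea_preranked, ora_hypergeometric,
                                     rank_genes)
from clustershift.io import read_gmt, write_gmt


def brute_force_es(genes, scores, gene_set, weight=1.0):
    """Independent loop-based running-sum oracle."""
    hits = set(gene_set)
    nr = sum(abs(s) ** weight for g, s in zip(genes, scores) if g in hits)
    n_hit = sum(1 for g in genes if g in hits)
    n = len(genes)
    run, best = 0.0, 0.0
    for g, s in zip(genes, scores):
        if g in hits:
            run += (abs(s) ** weight / nr) if nr > 0 else 1.0 / n_hit
        else:
            run -= 1.0 / (n - n_hit)
        if abs(run) > abs(best):
            best = run
    return best


class TestRanking:
    def _de(self, p, lfc, genes=None):
        genes = genes or [f"g{i}" for i in range(len(p))]
        return pd.DataFrame({"p": p, "log2FC": lfc}, index=genes)

    def test_sign_rule(self):
        ranked = rank_genes(self._de([0.01, 0.01, 1.0], [1.0, -1.0, 2.0]))
        assert np.isclose(ranked["g0"], 2.0)
        assert np.isclose(ranked["g1"], -2.0)
        assert np.isclose(ranked["g2"], 0.0)
        assert list(ranked.index) == ["g0", "g2", "g1"]

    def test_tie_break_by_abs_fold_change_then_name(self):
        ranked = rank_genes(self._de([0.1, 0.1, 0.1], [1.0, 3.0, 1.0],
                                     ["gb", "gc", "ga"]))
        assert list(ranked.index) == ["gc", "ga", "gb"]

    def test_zero_p_clamped(self):
        ranked = rank_genes(self._de([0.0, 0.5], [2.0, 1.0]))
        assert np.isfinite(ranked.to_numpy()).all()

    def test_missing_fold_change_rejected(self):
        with pytest.raises(ValidationError):
            rank_genes(self._de([0.1], [np.nan]))


class TestEnrichmentScore:
    def _ranked(self, scores, genes=None):
        genes = genes or [f"g{i}" for i in range(len(scores))]
        return pd.Series(scores, index=pd.Index(genes, name="gene"))

    def test_top_gene_set_scores_one(self):
        ranked = self._ranked([3.0, 2.0, 1.0, 0.5])
        es, _, leading = gsea_es(ranked, ["g0"])
        assert es == 1.0
        assert leading == ["g0"]

    def test_bottom_gene_set_scores_minus_one(self):
        ranked = self._ranked([3.0, 2.0, 1.0, 0.5])
        es, _, leading = gsea_es(ranked, ["g3"])
        assert np.isclose(es, -1.0)
        assert leading == ["g3"]

    def test_full_universe_set_scores_one(self):
        ranked = self._ranked([3.0, 2.0, 1.0])
        es, _, _ = gsea_es(ranked, ["g0", "g1", "g2"])
        assert np.isclose(es, 1.0)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            gsea_es(self._ranked([1.0, 0.5]), ["absent"])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(100)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            gene_set = list(rng.choice(genes, size=k, replace=False))
            es, _, _ = gsea_es(pd.Series(scores, index=genes), gene_set)
            oracle = brute_force_es(genes, scores, gene_set)
            assert abs(es - oracle) < 1e-12

    def test_reversing_ranked_list_negates_es(self):
        rng = np.random.default_rng(7)
        scores = np.sort(rng.normal(size=30))[::-1]
        genes = [f"g{i}" for i in range(30)]
        gene_set = list(rng.choice(genes, 8, replace=False))
        es_fwd, _, _ = gsea_es(pd.Series(scores, index=genes), gene_set)
        es_rev, _, _ = gsea_es(pd.Series(scores[::-1], index=genes[::-1]), gene_set)
        assert np.isclose(es_fwd, -es_rev, atol=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            scores = rng.normal(size=25)
            order = np.argsort(-scores)
            genes = [f"g{i}" for i in range(25)]
            ranked = pd.Series(scores[order], index=np.array(genes)[order])
            gene_set = list(rng.choice(genes, 6, replace=False))
            es, _, _ = gsea_es(ranked, gene_set)
            assert -1.0 <= es <= 1.0


class TestGSEAPreranked:
    def _fixture(self):
        rng = np.random.default_rng(21)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.normal(size=n))[::-1]
        ranked = pd.Series(scores, index=pd.Index(genes, name="gene"))
        sets = {"top": genes[:20]}
        for i in range(5):
            sets[f"decoy{i}"] = list(rng.choice(genes, 25, replace=False))
        return ranked, GeneSetCollection(sets)

    def test_planted_top_set_significant(self):
        ranked, sets = self._fixture()
        res = gsea_preranked(ranked, sets, n_perm=500, seed=0)
        assert res.table.loc["top", "NES"] > 0
        assert res.table.loc["top", "q"] < 0.05

    def test_determinism(self):
        ranked, sets = self._fixture()
        r1 = gsea_preranked(ranked, sets, n_perm=200, seed=5)
        r2 = gsea_preranked(ranked, sets, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_too_few_permutations_rejected(self):
        ranked, sets = self._fixture()
        with pytest.raises(ValidationError):
            gsea_preranked(ranked, sets, n_perm=10, seed=0)


def enumeration_ora_p(n_universe, set_size, query_size, overlap):
    """Exhaustively enumerate all queries of the given size and count those
    overlapping the set by at least ``overlap``."""
    universe = range(n_universe)
    members = set(range(set_size))
    hits = total = 0
    for query in itertools.combinations(universe, query_size):
        total += 1
        if len(members.intersection(query)) >= overlap:
            hits += 1
    return hits / total


class TestORA:
    def _collection(self, k, n_universe):
        return GeneSetCollection({"s": [f"g{i}" for i in range(k)]})

    def test_hand_example(self):
        # N=10, K=4, n=5, k=4 -> C(4,4) C(6,1) / C(10,5) = 6/252
        universe = [f"g{i}" for i in range(10)]
        query = [f"g{i}" for i in range(4)] + ["g9"]
        res = ora_hypergeometric(query, self._collection(4, 10), universe)
        assert np.isclose(res.loc["s", "p"], 6 / 252)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora_hypergeometric(["g8", "g9"], self._collection(4, 10), universe)
        assert np.isclose(res.loc["s", "p"], 1.0)

    def test_query_equals_universe_p_is_one(self):
        universe = [f"g{i}" for i in range(8)]
        res = ora_hypergeometric(universe, self._collection(3, 8), universe)
        assert np.isclose(res.loc["s", "p"], 1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        for n_uni in (5, 8, 11):
            universe = [f"g{i}" for i in range(n_uni)]
            for set_size in range(1, n_uni + 1):
                coll = self._collection(set_size, n_uni)
                for q_size in range(1, n_uni + 1):
                    query = [f"g{i}" for i in range(q_size)]
                    res = ora_hypergeometric(query, coll, universe)
                    k = len(set(query) & set(coll.sets["s"]))
                    oracle = enumeration_ora_p(n_uni, set_size, q_size, k)
                    assert abs(res.loc["s", "p"] - oracle) < 1e-12

    def test_bh_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(60)]
        sets = {f"s{i}": list(rng.choice(universe, 10, replace=False))
                for i in range(15)}
        query = list(rng.choice(universe, 20, replace=False))
        res = ora_hypergeometric(query, GeneSetCollection(sets), universe)
        assert (res["q"] >= res["p"] - 1e-15).all()
        ordered = res.sort_values("p")
        assert ordered["q"].is_monotonic_increasing

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            ora_hypergeometric(["zz"], self._collection(2, 5),
                               [f"g{i}" for i in range(5)])


class TestEnrichmentMap:
    def _results(self, names, qs):
        return pd.DataFrame({"q": qs}, index=pd.Index(names, name="set"))

    def test_disjoint_sets_no_edges(self):
        sets = GeneSetCollection({"A": ["a", "b"], "B": ["c", "d"]})
        g = build_enrichment_map(self._results(["A", "B"], [0.01, 0.01]), sets)
        assert set(g.nodes) == {"A", "B"}
        assert g.number_of_edges() == 0

    def test_duplicate_sets_edge_similarity_one(self):
        sets = GeneSetCollection({"A": ["a", "b"], "B": ["a", "b"]})
        g = build_enrichment_map(self._results(["A", "B"], [0.01, 0.01]), sets)
        assert np.isclose(g.edges[("A", "B")]["similarity"], 1.0)

    def test_hand_jaccard_edge(self):
        sets = GeneSetCollection({"A": ["a", "b", "c", "d"], "B": ["c", "d", "e", "f"]})
        g = build_enrichment_map(self._results(["A", "B"], [0.001, 0.001]), sets,
                                 sim_cut=0.25)
        assert np.isclose(g.edges[("A", "B")]["similarity"], 2 / 6)

    def test_insignificant_sets_excluded(self):
        sets = GeneSetCollection({"A": ["a"], "B": ["a"]})
        g = build_enrichment_map(self._results(["A", "B"], [0.2, 0.01]), sets)
        assert set(g.nodes) == {"B"}


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = {"s1": ["a", "b", "c"], "s2": ["d"]}
        p = tmp_path / "x.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("only_name\tdesc\n")
        with pytest.raises(ValidationError):
            read_gmt(p)

    def test_duplicate_genes_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("s\tna\ta\ta\n")
        with pytest.raises(ValidationError):
            read_gmt(p)
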