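"""Count I/O, TPM, TMM normalization and sample-level QC."""

import numpy as np
import pandas as pd
import pytest

from clustershift.expression import (CountMatrix, ExpressionMatrix,
                                     NormalizationFactors, ValidationError,
                                     compute_tpm, filter_expressed, normalize,
                                     qc_heatmap_matrix, qc_pca, read_counts,
                                     tmm_factors, write_counts, zscore_rows)

# TMM factors of the composition-biased toy (10% of genes 8-fold up in B),
# computed once with the reference implementation of the TMM method and frozen
EDGER_TOY_FACTORS = {"A": 1.2821751346, "B": 0.7799246554}


def _tmm_toy():
    rng = np.random.default_rng(20210510)
    n = 200
    base = rng.integers(20, 2000, size=n)
    a = base.copy()
    b = base.copy()
    up = rng.choice(n, size=20, replace=False)
    b[up] = b[up] * 8
    return CountMatrix(pd.DataFrame({"A": a, "B": b},
                                    index=[f"g{i}" for i in range(n)]))


class TestCountIO:
    def test_round_trip_bit_identical(self, tmp_path, tiny_counts):
        p = tmp_path / "c.tsv"
        lp = tmp_path / "l.tsv"
        write_counts(tiny_counts, p, lp)
        first = p.read_bytes()
        back = read_counts(p, lp)
        write_counts(back, p, lp)
        assert p.read_bytes() == first
        assert back.counts.equals(tiny_counts.counts)

    def test_zero_matrix_parses(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene\ts1\ts2\nga\t0\t0\ngb\t0\t0\ngc\t0\t0\n")
        cm = read_counts(p)
        assert (cm.counts.to_numpy() == 0).all()

    def test_negative_entry_names_cell(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene\ts1\ts2\nga\t1\t2\ngb\t-5\t3\n")
        with pytest.raises(ValidationError, match="'gb'.*'s1'"):
            read_counts(p)

    def test_duplicate_gene_listed(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene\ts1\nga\t1\nga\t2\n")
        with pytest.raises(ValidationError, match="ga"):
            read_counts(p)

    def test_expressed_filter(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0, 1, 5], "s2": [0, 0, 5]},
                                      index=["ga", "gb", "gc"]))
        assert list(filter_expressed(cm).genes) == ["gb", "gc"]
        assert list(filter_expressed(cm, min_count=5, min_samples=2).genes) == ["gc"]


class TestTPM:
    def test_hand_example(self, tiny_counts):
        tpm = compute_tpm(tiny_counts)
        assert np.allclose(tpm["s1"], [1e6 / 3, 2e6 / 3])

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        cm = CountMatrix(
            pd.DataFrame(rng.integers(0, 500, size=(30, 4)),
                         index=[f"g{i}" for i in range(30)],
                         columns=list("abcd")),
            pd.Series(rng.uniform(500, 5000, 30), index=[f"g{i}" for i in range(30)]))
        assert np.allclose(compute_tpm(cm).sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_sample_gives_zero_column(self):
        cm = CountMatrix(pd.DataFrame({"s1": [3, 1], "s2": [0, 0]}, index=["a", "b"]),
                         pd.Series([100.0, 200.0], index=["a", "b"]))
        assert (compute_tpm(cm)["s2"] == 0).all()

    def test_single_gene_is_million(self):
        cm = CountMatrix(pd.DataFrame({"s1": [7]}, index=["a"]),
                         pd.Series([321.0], index=["a"]))
        assert np.allclose(compute_tpm(cm).to_numpy(), 1e6)


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        col = np.arange(1, 51)
        cm = CountMatrix(pd.DataFrame({"A": col, "B": col},
                                      index=[f"g{i}" for i in range(50)]))
        f = tmm_factors(cm)
        assert np.allclose(f.factors, 1.0)

    def test_depth_scaling_leaves_factors_unit(self):
        # B = 2 × A: TMM corrects composition, not depth
        col = np.arange(1, 51)
        cm = CountMatrix(pd.DataFrame({"A": col, "B": 2 * col},
                                      index=[f"g{i}" for i in range(50)]))
        assert np.allclose(tmm_factors(cm).factors, 1.0, atol=1e-12)

    def test_matches_frozen_reference_on_composition_toy(self):
        f = tmm_factors(_tmm_toy()).factors
        for s, expected in EDGER_TOY_FACTORS.items():
            assert abs(f[s] - expected) / expected < 0.01

    def test_scale_invariance(self):
        cm = _tmm_toy()
        f1 = tmm_factors(cm).factors
        scaled = CountMatrix(cm.counts.assign(A=cm.counts["A"] * 7))
        f2 = tmm_factors(scaled).factors
        assert np.allclose(f1, f2, atol=1e-10)

    def test_zero_count_sample_rejected(self):
        cm = CountMatrix(pd.DataFrame({"A": [1, 2], "B": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValidationError, match="zero total"):
            tmm_factors(cm)


class TestNormalize:
    def _factors(self, cm):
        return NormalizationFactors(pd.Series(1.0, index=cm.samples), str(cm.samples[0]))

    def test_zero_tpm_maps_to_zero(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0, 10], "s2": [0, 10]}, index=["a", "b"]),
                         pd.Series([100.0, 100.0], index=["a", "b"]))
        expr = normalize(cm, self._factors(cm))
        assert expr.values.loc["a", "s1"] == 0.0

    def test_log2_of_tpm_plus_one(self):
        # gene a has TPM exactly 3 => log2(3+1) = 2
        cm = CountMatrix(
            pd.DataFrame({"s1": [3, 999997], "s2": [3, 999997]}, index=["a", "b"]),
            pd.Series([1000.0, 1000.0], index=["a", "b"]))
        expr = normalize(cm, self._factors(cm))
        assert np.isclose(expr.values.loc["a", "s1"], 2.0)

    def test_doubling_factor_halves_linear_values(self):
        rng = np.random.default_rng(1)
        cm = CountMatrix(
            pd.DataFrame(rng.integers(1, 300, (20, 2)),
                         index=[f"g{i}" for i in range(20)], columns=["s1", "s2"]),
            pd.Series(rng.uniform(500, 5000, 20), index=[f"g{i}" for i in range(20)]))
        e1 = normalize(cm, self._factors(cm), pseudocount=1e-9)
        f2 = NormalizationFactors(pd.Series({"s1": 2.0, "s2": 1.0}), "s2")
        e2 = normalize(cm, f2, pseudocount=1e-9)
        lin1 = 2.0 ** e1.values["s1"]
        lin2 = 2.0 ** e2.values["s1"]
        assert np.allclose(lin2, lin1 / 2.0, rtol=1e-6)

    def test_monotone_in_counts(self):
        cm = CountMatrix(pd.DataFrame({"s1": [1, 5, 20], "s2": [3, 3, 3]},
                                      index=list("abc")),
                         pd.Series([1000.0] * 3, index=list("abc")))
        col = normalize(cm, self._factors(cm)).values["s1"]
        assert col["a"] < col["b"] < col["c"]

    def test_missing_factor_errors(self):
        cm = CountMatrix(pd.DataFrame({"s1": [1], "s2": [2]}, index=["a"]),
                         pd.Series([100.0], index=["a"]))
        with pytest.raises(ValidationError, match="missing"):
            normalize(cm, NormalizationFactors(pd.Series({"s1": 1.0}), "s1"))


class TestQC:
    def _expr(self, arr, samples=None):
        df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                          columns=samples or [f"s{j}" for j in range(arr.shape[1])])
        return ExpressionMatrix(df, {"unit": "test"})

    def test_pca_identical_profiles_zero_variance(self):
        expr = self._expr(np.ones((5, 3)))
        _, pct = qc_pca(expr)
        assert np.allclose(pct, 0)

    def test_pca_rank_one(self):
        arr = np.zeros((4, 3))
        arr[0] = [0.0, 1.0, 2.0]
        _, pct = qc_pca(self._expr(arr))
        assert np.isclose(pct[0], 100.0)

    def test_pca_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(50, 6))
        _, pct = qc_pca(self._expr(arr))
        centred = (arr - arr.mean(axis=1, keepdims=True)).T
        evals = np.linalg.eigvalsh(centred @ centred.T)[::-1]
        oracle = 100.0 * evals / evals.sum()
        assert np.allclose(pct, oracle[: len(pct)], atol=1e-8)

    def test_zscore_hand_example(self):
        z, flat = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                                           columns=list("abc")))
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])
        assert len(flat) == 0

    def test_heatmap_constant_row_flagged(self):
        arr = np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        out = qc_heatmap_matrix(self._expr(arr))
        assert out["zero_variance_genes"] == ["g0"]
        assert np.allclose(out["zscores"].loc["g0"], 0.0)
        assert np.allclose(out["zscores"].loc["g1"], [-1.0, 0.0, 1.0])

    def test_heatmap_identical_samples_ok(self):
        arr = np.tile([[1.0], [2.0], [5.0]], (1, 4))
        out = qc_heatmap_matrix(self._expr(arr))
        assert sorted(out["col_order"].tolist()) == [0, 1, 2, 3]
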