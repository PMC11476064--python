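"""Container invariants, TSV round trips, quantile normalisation, z-scoring,
PCA and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gradesig.core_io import (
    ExpressionMatrix,
    ExpressionMatrixError,
    PhenotypeTable,
    hier_cluster,
    pca_embed,
    quantile_normalize,
    read_expression_matrix,
    write_expression_matrix,
    read_phenotype_table,
    write_phenotype_table,
    zscore_rows,
)


class TestExpressionIO:
    def test_identity_load(self, tmp_path, tiny_expr):
        path = tmp_path / "expr.tsv"
        write_expression_matrix(tiny_expr, path)
        loaded = read_expression_matrix(path)
        assert loaded.gene_ids == ["g1", "g2", "g3"]
        assert loaded.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(loaded.values, tiny_expr.values)

    def test_round_trip_12_significant_digits(self, tmp_path):
        rng = np.random.default_rng(5)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(20)],
            [f"s{j}" for j in range(7)],
            rng.uniform(4, 13, size=(20, 7)),
        )
        path = tmp_path / "m.tsv"
        write_expression_matrix(m, path)
        back = read_expression_matrix(path)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-11)

    def test_na_cell_is_fatal_with_context(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1.5\tNA\ng2\t2.0\t3.0\n")
        with pytest.raises(ExpressionMatrixError, match="g1.*s2"):
            read_expression_matrix(path)

    def test_duplicate_gene_ids_fatal(self):
        with pytest.raises(ExpressionMatrixError, match="duplicate gene"):
            ExpressionMatrix(["g1", "g1"], ["s1"], [[1.0], [2.0]])

    def test_transpose_recovery_requires_flag_and_phenotype(self, tmp_path):
        pheno = PhenotypeTable(
            pd.DataFrame({"sample_id": ["s1", "s2"], "grade": ["grade2", "grade3"]})
        )
        path = tmp_path / "t.tsv"
        # file written samples-in-rows
        path.write_text("sample_id\tg1\tg2\ns1\t1\t2\ns2\t3\t4\n")
        m = read_expression_matrix(path, transpose_allowed=True, pheno=pheno)
        assert m.gene_ids == ["g1", "g2"]
        assert m.sample_ids == ["s1", "s2"]

    def test_phenotype_round_trip_and_invariants(self, tmp_path):
        df = pd.DataFrame(
            {"sample_id": ["a", "b"], "grade": ["grade2", "grade3"],
             "months": [12.0, 30.0], "event": [1, 0]}
        )
        pheno = PhenotypeTable(df)
        path = tmp_path / "pheno.tsv"
        write_phenotype_table(pheno, path)
        back = read_phenotype_table(path)
        pd.testing.assert_frame_equal(back.data, pheno.data, check_dtype=False)
        with pytest.raises(ValueError, match="event"):
            PhenotypeTable(pd.DataFrame(
                {"sample_id": ["a"], "grade": ["grade2"], "months": [5.0], "event": [np.nan]}
            ))


class TestQuantileNormalize:
    def test_two_column_hand_example(self, tiny_expr):
        out = quantile_normalize(tiny_expr)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values, expected)

    def test_single_sample_unchanged(self):
        m = ExpressionMatrix(["a", "b"], ["s"], [[2.0], [1.0]])
        np.testing.assert_array_equal(quantile_normalize(m).values, m.values)

    def test_identical_columns_fixed_point(self):
        m = ExpressionMatrix(["a", "b", "c"], ["s1", "s2"], [[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]])
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_ties_get_mean_of_reference_span(self):
        # column 1 has a tie at rank 1-2: both get mean(ref[0], ref[1])
        m = ExpressionMatrix(["a", "b", "c"], ["s1", "s2"], [[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
        out = quantile_normalize(m)
        ref = np.array([1.0, 1.5, 4.0])  # per-rank means of sorted columns
        np.testing.assert_allclose(out.values[:, 1], ref)
        np.testing.assert_allclose(out.values[:2, 0], [(ref[0] + ref[1]) / 2] * 2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8), st.integers(3, 12))
    def test_columns_share_one_distribution(self, seed, n_samples, n_genes):
        rng = np.random.default_rng(seed)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(n_samples)],
            rng.normal(8, 2, size=(n_genes, n_samples)),
        )
        out = quantile_normalize(m).values
        # continuous draws: no ties, so sorted columns are exactly equal
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, n_samples):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)


class TestZscoreRows:
    def test_hand_example_sample_sd(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], [[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(zscore_rows(m).values, [[-1.0, 0.0, 1.0]])

    def test_constant_row_zeroed_with_warning(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], [[5.0, 5.0, 5.0]])
        with pytest.warns(RuntimeWarning, match="constant"):
            out = zscore_rows(m)
        np.testing.assert_array_equal(out.values, [[0.0, 0.0, 0.0]])

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"s{j}" for j in range(9)],
            rng.normal(size=(5, 9)),
        )
        once = zscore_rows(m)
        twice = zscore_rows(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


class TestPca:
    def test_two_samples_single_axis(self):
        m = ExpressionMatrix(["g1", "g2"], ["s1", "s2"], [[0.0, 1.0], [0.0, 2.0]])
        _, frac = pca_embed(m, 1)
        assert frac[0] == pytest.approx(1.0)

    def test_rank_one_data_one_component(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"s{j}" for j in range(8)],
            np.outer(rng.normal(size=5), rng.normal(size=8)),
        )
        _, frac = pca_embed(m, 2)
        assert frac[0] == pytest.approx(1.0, abs=1e-8)

    def test_duplicating_every_sample_keeps_fractions(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 5))
        m = ExpressionMatrix([f"g{i}" for i in range(6)], [f"s{j}" for j in range(5)], vals)
        m2 = ExpressionMatrix(
            [f"g{i}" for i in range(6)],
            [f"s{j}" for j in range(5)] + [f"t{j}" for j in range(5)],
            np.hstack([vals, vals]),
        )
        _, f1 = pca_embed(m, 3)
        _, f2 = pca_embed(m2, 3)
        np.testing.assert_allclose(f2, f1, atol=1e-10)

    def test_fractions_match_covariance_eigenvalues(self):
        # brute-force oracle: eigenvalues of the gene-centred sample covariance
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(9, 6))
        m = ExpressionMatrix([f"g{i}" for i in range(9)], [f"s{j}" for j in range(6)], vals)
        X = vals.T - vals.T.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1]
        expected = eig[:4] / eig.sum()
        _, frac = pca_embed(m, 4)
        np.testing.assert_allclose(frac, expected, atol=1e-8)

    def test_component_cap(self, tiny_expr):
        with pytest.raises(ValueError):
            pca_embed(tiny_expr, 2)  # min(3 genes, 2 samples - 1) = 1


class TestHierCluster:
    def test_identical_samples_merge_first_at_zero(self):
        vals = np.array([[1.0, 1.0, 9.0], [2.0, 2.0, 7.0]])
        m = ExpressionMatrix(["g1", "g2"], ["a", "b", "c"], vals)
        Z, _ = hier_cluster(m, axis="samples")
        assert Z[0, 2] == pytest.approx(0.0)
        assert sorted(Z[0, :2].astype(int)) == [0, 1]

    def test_upgma_toy_heights(self):
        m = ExpressionMatrix(["g"], ["x", "y", "z"], [[0.0, 1.0, 10.0]])
        Z, _ = hier_cluster(m, axis="samples", linkage="average")
        np.testing.assert_allclose(Z[:, 2], [1.0, 9.5])

    def test_merge_heights_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(4, 7))
        m = ExpressionMatrix([f"g{i}" for i in range(4)], [f"s{j}" for j in range(7)], vals)
        perm = rng.permutation(7)
        m_perm = ExpressionMatrix(
            m.gene_ids, [m.sample_ids[j] for j in perm], vals[:, perm]
        )
        Z1, _ = hier_cluster(m, axis="samples")
        Z2, _ = hier_cluster(m_perm, axis="samples")
        np.testing.assert_allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]), atol=1e-12)

    def test_zero_variance_item_dropped_under_correlation(self):
        vals = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [3.0, 1.0, 2.0]])
        m = ExpressionMatrix(["g1", "g2", "g3"], ["a", "b", "c"], vals)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            _, leaves = hier_cluster(m, axis="genes", metric="correlation")
        assert set(leaves) == {"g1", "g3"}
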