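"""Imputation, encoding, scaling, correlation filtering and integration."""

import numpy as np
import pandas as pd
import pytest

from metasurv.matrix import CATEGORICAL, NUMERIC, OmicsMatrix
from metasurv.preprocess import (
    drop_leakage,
    encode_labels,
    filter_correlated,
    impute_knn,
    integrate,
    preprocess_block,
    zscore,
)

from conftest import simple_matrix


def corr_columns(target_r, n=400, seed=0):
    """Columns whose *sample* correlation matrix equals ``target_r`` exactly."""
    rng = np.random.default_rng(seed)
    C = np.array(target_r)
    L = np.linalg.cholesky(C)
    Z = rng.normal(size=(n, C.shape[0]))
    X = Z @ L.T
    # make the *sample* correlation exact by whitening first
    Zw = np.linalg.solve(np.linalg.cholesky(np.corrcoef(Z.T)), Z.T).T
    return Zw @ L.T


class TestImputeKnn:
    def test_nearest_donor_value_used(self):
        m = simple_matrix(np.array([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]]))
        out, rep = impute_knn(m)
        # donor distances over observed features: row1 at 0, row2 at sqrt(64+49)
        assert out.data.iloc[0, 2] == 3.0
        assert rep.imputed_cell_count == 1

    def test_no_missing_is_identity(self, rng):
        m = simple_matrix(rng.normal(size=(5, 3)))
        out, rep = impute_knn(m)
        pd.testing.assert_frame_equal(out.data, m.data)
        assert rep.imputed_cell_count == 0

    def test_equidistant_donors_take_lowest_row_index(self):
        # rows 1 and 2 are equidistant from row 0; donor values differ
        m = simple_matrix(
            np.array([[0.0, np.nan], [1.0, 10.0], [-1.0, 20.0]])
        )
        out, _ = impute_knn(m)
        assert out.data.iloc[0, 1] == 10.0

    def test_all_missing_column_raises_with_name(self):
        m = simple_matrix(np.array([[1.0, np.nan], [2.0, np.nan]]))
        with pytest.raises(ValueError, match="f1"):
            impute_knn(m)

    def test_row_without_shared_features_falls_back_to_median(self):
        # row 0 observes only f0; donors observe only f1 -> median fallback for f1
        m = simple_matrix(
            np.array(
                [
                    [5.0, np.nan],
                    [np.nan, 1.0],
                    [np.nan, 3.0],
                ]
            )
        )
        out, _ = impute_knn(m)
        assert out.data.iloc[0, 1] == 2.0  # median of (1, 3)

    def test_categorical_cells_untouched(self):
        m = simple_matrix(
            np.array([["a", 1.0], ["b", np.nan], ["a", 5.0]], dtype=object),
            kinds={"f0": CATEGORICAL, "f1": NUMERIC},
        )
        out, _ = impute_knn(m)
        assert list(out.data["f0"]) == ["a", "b", "a"]
        assert not out.data["f1"].isna().any()


class TestEncodeLabels:
    def test_lexicographic_mapping(self):
        m = simple_matrix(
            np.array([["b"], ["a"], ["b"]], dtype=object), kinds={"f0": CATEGORICAL}
        )
        out, rep = encode_labels(m)
        assert list(out.data["f0"]) == [1.0, 0.0, 1.0]
        assert rep.encoded_feature_names["f0"] == {"a": 0, "b": 1}
        assert out.feature_kinds["f0"] == NUMERIC

    def test_all_numeric_unchanged(self, rng):
        m = simple_matrix(rng.normal(size=(4, 2)))
        out, rep = encode_labels(m)
        pd.testing.assert_frame_equal(out.data, m.data)
        assert rep.encoded_feature_names == {}

    def test_single_level_column_becomes_all_zeros(self):
        m = simple_matrix(
            np.array([["x"], ["x"], ["x"]], dtype=object), kinds={"f0": CATEGORICAL}
        )
        out, _ = encode_labels(m)
        assert (out.data["f0"] == 0.0).all()
        # flagged zero_variance downstream
        _, rep = zscore(out)
        assert ("f0", "zero_variance") in rep.dropped_features


class TestDropLeakage:
    def test_vital_status_column_removed(self, rng):
        m = simple_matrix(rng.normal(size=(3, 2)), columns=["vital_status", "age"])
        out, rep = drop_leakage(m, ["vital_status"])
        assert "vital_status" not in out.feature_names
        assert ("vital_status", "vital_status") in rep.dropped_features

    def test_empty_list_is_identity(self, rng):
        m = simple_matrix(rng.normal(size=(3, 2)))
        out, _ = drop_leakage(m, [])
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_absent_name_warns_not_errors(self, rng):
        m = simple_matrix(rng.normal(size=(3, 2)))
        with pytest.warns(UserWarning, match="not present"):
            out, rep = drop_leakage(m, ["f0", "nope"])
        assert list(out.feature_names) == ["f1"]


class TestZscore:
    def test_closed_form_three_values(self):
        m = simple_matrix(np.array([[1.0], [2.0], [3.0]]))
        out, _ = zscore(m)
        np.testing.assert_allclose(out.data["f0"], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped(self):
        m = simple_matrix(np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]]))
        out, rep = zscore(m)
        assert list(out.feature_names) == ["f0"]
        assert ("f1", "zero_variance") in rep.dropped_features

    def test_idempotent_up_to_tolerance(self, rng):
        m = simple_matrix(rng.normal(size=(50, 4)))
        once, _ = zscore(m)
        twice, _ = zscore(once)
        np.testing.assert_allclose(once.values(), twice.values(), atol=1e-10)

    def test_standardized_invariant_holds(self, rng):
        m = simple_matrix(rng.normal(2.0, 3.0, size=(30, 5)))
        out, _ = zscore(m)
        X = out.values()
        assert np.abs(X.mean(axis=0)).max() < 1e-8
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-8)


class TestFilterCorrelated:
    def test_duplicate_column_dropped(self, rng):
        a = rng.normal(size=100)
        c = rng.normal(size=100)
        m = simple_matrix(np.column_stack([a, a, c]))
        out, rep = filter_correlated(m)
        assert list(out.feature_names) == ["f0", "f2"]
        assert ("f1", "high_correlation") in rep.dropped_features

    def test_orthogonal_columns_all_survive(self, rng):
        X = rng.normal(size=(500, 6))
        m = simple_matrix(X)
        out, _ = filter_correlated(m)
        assert out.shape[1] == 6

    def test_greedy_chain_keeps_a_and_c(self):
        # corr(a,b)=0.9, corr(b,c)=0.9, corr(a,c)=0.68 (the smallest third
        # correlation compatible with the first two is 0.62): greedy scan
        # drops b, then c survives because its correlation to retained a
        # is below the 0.7 threshold
        X = corr_columns([[1.0, 0.9, 0.68], [0.9, 1.0, 0.9], [0.68, 0.9, 1.0]])
        m = simple_matrix(X, columns=["a", "b", "c"])
        out, rep = filter_correlated(m, threshold=0.7)
        assert list(out.feature_names) == ["a", "c"]
        assert ("b", "high_correlation") in rep.dropped_features

    def test_anticorrelation_counts_as_redundant(self, rng):
        a = rng.normal(size=100)
        m = simple_matrix(np.column_stack([a, -a]))
        out, _ = filter_correlated(m)
        assert list(out.feature_names) == ["f0"]

    def test_no_surviving_pair_above_threshold(self, rng):
        X = rng.normal(size=(60, 10))
        X[:, 3] = 0.8 * X[:, 0] + 0.2 * rng.normal(size=60)
        X[:, 7] = -0.9 * X[:, 2] + 0.1 * rng.normal(size=60)
        out, _ = filter_correlated(simple_matrix(X), threshold=0.7)
        R = np.corrcoef(out.values().T)
        np.fill_diagonal(R, 0.0)
        assert np.abs(R).max() <= 0.7

    def test_idempotence(self, rng):
        X = rng.normal(size=(80, 8))
        X[:, 1] = X[:, 0]
        once, _ = filter_correlated(simple_matrix(X))
        twice, _ = filter_correlated(once)
        assert list(once.feature_names) == list(twice.feature_names)

    def test_independent_features_rarely_dropped(self):
        # rho = 0, n >> p: expected drop count ~ 0 (<= 1% over 10 seeds)
        drops = 0
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = simple_matrix(rng.normal(size=(800, 30)))
            out, _ = filter_correlated(m, threshold=0.7)
            drops += 30 - out.shape[1]
            total += 30
        assert drops / total <= 0.01


class TestIntegrate:
    def test_identical_blocks_collapse_to_one_column(self, rng):
        a = rng.normal(size=20)
        m1 = simple_matrix(a[:, None], columns=["x"], block="b1")
        m2 = simple_matrix(a[:, None].copy(), columns=["y"], block="b2")
        out, rep = integrate([m1, m2])
        assert out.shape[1] == 1
        assert ("y", "high_correlation") in rep.dropped_features

    def test_disjoint_patient_sets_raise(self, rng):
        m1 = simple_matrix(rng.normal(size=(3, 2)))
        m2 = simple_matrix(rng.normal(size=(3, 2)))
        m2.data.index = ["Q0", "Q1", "Q2"]
        with pytest.raises(ValueError, match="no patients shared"):
            integrate([m1, m2])

    def test_uncorrelated_blocks_keep_all_columns(self, rng):
        m1 = simple_matrix(rng.normal(size=(300, 5)), columns=[f"a{i}" for i in range(5)])
        m2 = simple_matrix(rng.normal(size=(300, 3)), columns=[f"b{i}" for i in range(3)])
        out, _ = integrate([m1, m2])
        assert out.shape[1] == 8

    def test_name_collision_gets_block_prefix(self, rng):
        m1 = simple_matrix(rng.normal(size=(50, 1)), columns=["x"], block="b1")
        m2 = simple_matrix(rng.normal(size=(50, 1)), columns=["x"], block="b2")
        out, _ = integrate([m1, m2])
        assert set(out.feature_names) == {"x", "b2:x"}


class TestPipelineOrder:
    def test_stage_provenance_recorded_in_order(self, rng):
        X = rng.normal(size=(40, 4))
        X[0, 1] = np.nan
        m = simple_matrix(X)
        _, report = preprocess_block(m)
        assert report.stages == [
            "impute",
            "encode",
            "drop_leakage",
            "zscore",
            "filter_correlated",
        ]

    def test_output_is_standardized_and_complete(self, rng):
        X = rng.normal(size=(60, 5))
        X[2, 0] = np.nan
        m = simple_matrix(X)
        out, _ = preprocess_block(m)
        V = out.values()
        assert not np.isnan(V).any()
        assert np.abs(V.mean(axis=0)).max() < 1e-8
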