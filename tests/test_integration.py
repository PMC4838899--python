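import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from otomics import (
    ValidationError,
    cluster_of_clusters,
    crosstab_association,
    encode_partitions,
    mirna_preprocess,
)


def _part(d, name):
    return pd.Series(d, name=name, dtype=float)


class TestEncodePartitions:
    def test_five_four_four_classes_give_13_columns(self):
        samples = [f"s{i}" for i in range(20)]
        p1 = pd.Series(np.arange(20) % 5, index=samples, name="mrna")
        p2 = pd.Series(np.arange(20) % 4, index=samples, name="meth")
        p3 = pd.Series(np.arange(20) % 4, index=samples, name="mirna")
        ind = encode_partitions([p1, p2, p3])
        assert ind.shape == (20, 13)

    def test_unclassified_sample_gets_na_block(self):
        p1 = _part({"a": 1, "b": 2, "c": 1}, "mrna")
        p2 = _part({"a": 1, "b": 2}, "meth")
        ind = encode_partitions([p1, p2])
        assert ind.loc["c", ["meth:1.0", "meth:2.0"]].isna().all()
        assert ind.loc["c", ["mrna:1.0", "mrna:2.0"]].notna().all()

    def test_one_hot_row(self):
        p1 = pd.Series([2, 1, 3, 4, 5], index=list("abcde"), name="mrna")
        p2 = pd.Series([1, 1, 2, 2, 1], index=list("abcde"), name="x")
        ind = encode_partitions([p1, p2])
        row = ind.loc["a", [f"mrna:{c}" for c in (1, 2, 3, 4, 5)]]
        assert row.tolist() == [0.0, 1.0, 0.0, 0.0, 0.0]
        # each partition block sums to exactly 1 for classified samples
        assert ind.filter(like="mrna:").sum(axis=1).eq(1.0).all()

    def test_single_class_partition_rejected(self):
        p1 = _part({"a": 1, "b": 1}, "bad")
        p2 = _part({"a": 1, "b": 2}, "ok")
        with pytest.raises(ValidationError):
            encode_partitions([p1, p2])


class TestClusterOfClusters:
    def test_identical_partitions_are_reproduced(self):
        samples = [f"s{i}" for i in range(30)]
        truth = pd.Series(np.arange(30) % 3, index=samples)
        parts = [truth.rename(f"om{i}").astype(float) for i in range(3)]
        res = cluster_of_clusters(encode_partitions(parts), k_range=[2, 3, 4],
                                  n_iter=100, seed=0)
        assert res.selected_k == 3
        assert adjusted_rand_score(truth, res.selected_labels()) == 1.0

    def test_nested_partitions_recover_finer(self):
        samples = [f"s{i}" for i in range(40)]
        fine = pd.Series(np.arange(40) % 4, index=samples, name="fine").astype(float)
        coarse = (fine % 2).rename("coarse")
        res = cluster_of_clusters(encode_partitions([coarse, fine]),
                                  k_range=[2, 3, 4, 5], n_iter=200, seed=0)
        assert adjusted_rand_score(fine, res.labels[4]) == 1.0

    def test_relabelling_inputs_leaves_result_unchanged(self):
        samples = [f"s{i}" for i in range(24)]
        truth = pd.Series(np.arange(24) % 3, index=samples)
        rng = np.random.default_rng(0)
        parts = []
        for i in range(3):
            lab = truth.astype(float).copy()
            noisy = rng.random(24) < 0.1
            lab[noisy] = rng.integers(0, 3, noisy.sum())
            parts.append(lab.rename(f"om{i}"))
        res1 = cluster_of_clusters(encode_partitions(parts), k_range=[2, 3, 4],
                                   n_iter=100, seed=1)
        remap = {0.0: 7.0, 1.0: 5.0, 2.0: 9.0}
        parts2 = [parts[0].map(remap).rename("om0"), *parts[1:]]
        res2 = cluster_of_clusters(encode_partitions(parts2), k_range=[2, 3, 4],
                                   n_iter=100, seed=1)
        assert adjusted_rand_score(res1.selected_labels(), res2.selected_labels()) == 1.0

    def test_all_na_omic_block_does_not_change_result(self):
        samples = [f"s{i}" for i in range(24)]
        truth = pd.Series(np.arange(24) % 3, index=samples).astype(float)
        ind = encode_partitions([truth.rename("a"), truth.rename("b")])
        extra = ind.copy()
        for c in ("ghost:1", "ghost:2", "ghost:3"):
            extra[c] = np.nan
        r1 = cluster_of_clusters(ind, k_range=[2, 3, 4], n_iter=100, seed=2)
        r2 = cluster_of_clusters(extra, k_range=[2, 3, 4], n_iter=100, seed=2)
        pd.testing.assert_series_equal(r1.selected_labels(), r2.selected_labels())

    def test_fully_unclassified_sample_excluded_with_warning(self):
        p1 = _part({"a": 1, "b": 2, "c": np.nan, "d": 1}, "x")
        p2 = _part({"a": 1, "b": 2, "c": np.nan, "d": 1}, "y")
        ind = encode_partitions([p1, p2])
        with pytest.warns(UserWarning, match="unclassified"):
            res = cluster_of_clusters(ind, k_range=[2, 3], n_iter=20, seed=0)
        assert "c" not in res.selected_labels().index


class TestMirnaPreprocess:
    def test_expression_filter(self):
        counts = pd.DataFrame(
            {"s1": [12, 12, 500], "s2": [11, 9, 500], "s3": [0, 9, 500]},
            index=["keep", "drop", "high"],
        )
        m = mirna_preprocess(counts)
        assert "keep" in m.values.index      # >10 reads in two samples
        assert "drop" not in m.values.index  # >10 reads in only one sample
        assert "high" in m.values.index

    def test_centring_gives_zero_feature_means(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 8)),
            index=[f"m{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(8)],
        )
        m = mirna_preprocess(counts)
        assert np.allclose(m.values.mean(axis=1), 0.0, atol=1e-12)

    def test_normalization_order_log2_then_depth(self):
        counts = pd.DataFrame({"s1": [100, 300], "s2": [100, 700]}, index=["a", "b"])
        m = mirna_preprocess(counts)
        tot = counts.sum()
        expected = np.log2(counts + 1).div(tot / 1e6, axis=1)
        expected = expected.sub(expected.mean(axis=1), axis=0)
        assert np.allclose(m.values, expected)

    def test_zero_read_sample_excluded(self):
        counts = pd.DataFrame({"s1": [20, 30], "s2": [0, 0], "s3": [15, 40]},
                              index=["a", "b"])
        with pytest.warns(UserWarning, match="zero total"):
            m = mirna_preprocess(counts)
        assert "s2" not in m.values.columns

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"s1": [-1, 5]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            mirna_preprocess(counts)


class TestCrosstabAssociation:
    def test_perfect_association_reaches_theoretical_maximum(self):
        # identical 3-class partitions, 30 balanced samples:
        # chi-square = n * (min(r, c) - 1) = 60
        labels = pd.Series(np.arange(30) % 3, index=[f"s{i}" for i in range(30)])
        _, stat, p = crosstab_association(labels, labels)
        assert stat == pytest.approx(60.0)
        assert p < 1e-10

    def test_two_by_two_diagonal_table(self):
        a = pd.Series([0] * 10 + [1] * 10, index=[f"s{i}" for i in range(20)])
        _, stat, _ = crosstab_association(a, a)
        assert stat == pytest.approx(20.0)

    def test_independent_partitions_give_uniformish_p(self):
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            a = pd.Series(rng.integers(0, 3, 60), index=[f"s{i}" for i in range(60)])
            b = pd.Series(rng.integers(0, 3, 60), index=a.index)
            ps.append(crosstab_association(a, b)[2])
        assert 0.35 < np.median(ps) < 0.65

    def test_degenerate_table_rejected(self):
        a = pd.Series({"x": 1, "y": 1, "z": 2})
        b = pd.Series({"x": 1, "y": 1, "z": np.nan})
        with pytest.raises(ValidationError):
            crosstab_association(a, b)
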