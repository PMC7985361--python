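from itertools import combinations

import numpy as np
import pytest

from ramanbayes.clustering import (
    compare_partitions,
    fit_kmeans,
    map_cluster_labels,
)
from ramanbayes.errors import ValidationError
from ramanbayes.features import FeatureMatrix


def fm(values, feature_set="FPHW", labels=None):
    values = np.atleast_2d(np.asarray(values, float))
    n, k = values.shape
    if labels is None:
        labels = [f"band{j}" for j in range(k)]
    return FeatureMatrix(
        target_ids=[f"t{i}" for i in range(n)],
        feature_set=feature_set,
        values=values,
        band_labels=labels,
    )


def exhaustive_best_inertia(X):
    """Global minimum within-cluster squared-Euclidean inertia over all
    2-partitions (both clusters non-empty), by direct enumeration."""
    n = len(X)
    best = np.inf
    for size in range(1, n // 2 + 1):
        for group in combinations(range(n), size):
            a = np.array(group)
            b = np.setdiff1d(np.arange(n), a)
            ia = ((X[a] - X[a].mean(axis=0)) ** 2).sum()
            ib = ((X[b] - X[b].mean(axis=0)) ** 2).sum()
            best = min(best, ia + ib)
    return best


class TestFitKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.5, (20, 9))
        b = rng.normal(10.0, 0.5, (20, 9))
        model = fit_kmeans(fm(np.vstack([a, b])), seed=0)
        assignments = model.assignments
        assert len(set(assignments[:20])) == 1
        assert len(set(assignments[20:])) == 1
        assert assignments[0] != assignments[-1]

    def test_matches_exhaustive_global_minimum_on_8_points(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (8, 3))
        model = fit_kmeans(fm(X), seed=0)
        assert model.inertia == pytest.approx(exhaustive_best_inertia(X), rel=1e-9)

    def test_two_distinct_points_inertia_zero(self):
        model = fit_kmeans(fm([[0.0, 0.0], [1.0, 1.0]]), seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)
        assert set(model.assignments) == {0, 1}

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (12, 4))
        m1 = fit_kmeans(fm(X), seed=5)
        m2 = fit_kmeans(fm(X), seed=5)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_identical_rows_rejected(self):
        with pytest.raises(ValidationError):
            fit_kmeans(fm(np.ones((5, 3))), seed=0)


class TestMapClusterLabels:
    def _hw_matrix(self):
        labels = [
            "796", "828", "1048", "1300", "1437", "1654",
            "2853", "2896", "2937",
        ]
        return labels

    def test_low_hw_centroid_is_tumor(self):
        # 2 tight groups: one with strong HW flux, one collapsed
        strong = np.concatenate([np.full(6, 0.1), np.full(3, 0.9)])
        weak = np.concatenate([np.full(6, 0.1), np.full(3, 0.1)])
        X = np.vstack([strong + 1e-3, strong, weak, weak + 1e-3])
        model = fit_kmeans(fm(X, "FPHW", self._hw_matrix()), seed=0)
        model = map_cluster_labels(model, feature_set="FPHW")
        labels = model.labels()
        assert labels[0] == "healthy" and labels[2] == "tumor"

    def test_fp_only_larger_796_828_ratio_is_tumor(self):
        # columns: 796, 828, then 4 more FP bands
        healthy = np.array([0.5, 1.0, 0.2, 0.2, 0.2, 0.2])
        tumor = np.array([1.4, 1.0, 0.2, 0.2, 0.2, 0.2])
        X = np.vstack([healthy, healthy * 1.01, tumor, tumor * 1.01])
        model = fit_kmeans(fm(X, "FP"), seed=0)
        model = map_cluster_labels(model, feature_set="FP")
        labels = model.labels()
        assert labels[0] == "healthy" and labels[2] == "tumor"

    def test_permutation_invariance(self):
        # relabeling clusters never changes healthy/tumor semantics
        strong = np.concatenate([np.full(6, 0.1), np.full(3, 0.9)])
        weak = np.concatenate([np.full(6, 0.1), np.full(3, 0.1)])
        X = np.vstack([strong, strong * 1.01, weak, weak * 1.01])
        model = fit_kmeans(fm(X, "FPHW", self._hw_matrix()), seed=0)
        flipped = type(model)(
            k=2,
            centroids=model.centroids[::-1].copy(),
            assignments=1 - model.assignments,
            inertia=model.inertia,
            seed=model.seed,
            feature_set=model.feature_set,
        )
        l1 = map_cluster_labels(model, feature_set="FPHW").labels()
        l2 = map_cluster_labels(flipped, feature_set="FPHW").labels()
        assert l1 == l2

    def test_generator_ground_truth_recovered_all_sets(self, separated_dataset):
        from ramanbayes.features import build_feature_matrix
        from ramanbayes.preprocess import preprocess_all

        sset, manifest = separated_dataset
        pre = preprocess_all(sset)
        truth = manifest["true_class"].tolist()
        for tag in ("FPHW", "FP", "HW"):
            m = map_cluster_labels(
                fit_kmeans(build_feature_matrix(pre, feature_set=tag), seed=0)
            )
            assert m.labels() == truth, f"feature set {tag}"


class TestComparePartitions:
    def test_identical_labelings(self):
        labs = ["tumor"] * 5 + ["healthy"] * 5
        c = compare_partitions(labs, labs)
        assert (c.TP, c.FN, c.TN, c.FP) == (5, 0, 5, 0)

    def test_all_tumor_vs_all_healthy(self):
        c = compare_partitions(["tumor"] * 4, ["healthy"] * 4)
        assert (c.TN, c.FP) == (0, 4)

    def test_printed_disagreement_structure(self):
        # 49 tumor-reference targets of which 4 predicted healthy; all 25
        # healthy-reference targets predicted healthy
        reference = ["tumor"] * 49 + ["healthy"] * 25
        predicted = ["healthy"] * 4 + ["tumor"] * 45 + ["healthy"] * 25
        c = compare_partitions(predicted, reference)
        assert (c.TP, c.FN, c.TN, c.FP) == (45, 4, 25, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_partitions(["tumor"], ["tumor", "healthy"])
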