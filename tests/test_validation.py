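"""Block-wise CV, grid search and the regression baselines."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from myoknn import (KnnConfig, LabeledDataset, ReductionConfig, SyntheticConfig,
                    blockwise_cv, generate_envelope_dataset, grid_search,
                    max_k, median_heuristic, rff_map, rr_fit, rr_predict,
                    rr_rff_fit, rr_rff_predict)


class TestBlockwiseCv:
    def test_one_fold_per_block(self, small_world):
        _, data = small_world
        res = blockwise_cv(data, KnnConfig(k=1))
        assert len(res.fold_accuracies) == len(np.unique(data.blocks))
        assert res.mean_accuracy == pytest.approx(
            np.mean(res.fold_accuracies))

    def test_separable_world_is_perfect(self, small_world):
        _, data = small_world
        assert blockwise_cv(data, KnnConfig(k=1)).mean_accuracy == 1.0

    def test_k_rel_bookkeeping(self, small_world):
        _, data = small_world
        res = blockwise_cv(data, KnnConfig(k=3))
        assert res.k_rel == pytest.approx(3 / data.n_samples)

    def test_k_bound_names_the_limit(self, small_world):
        _, data = small_world
        bound = max_k(data)
        assert bound == data.n_samples - 30  # largest block has 30 samples
        with pytest.raises(ValueError, match=str(bound)):
            blockwise_cv(data, KnnConfig(k=bound + 1))

    def test_shuffled_labels_hit_chance_level(self):
        cfg = SyntheticConfig(classes=("rs", "pw", "pn", "fl", "ex"),
                              repetitions=4, samples_per_rep=50, seed=8)
        data = generate_envelope_dataset(cfg)
        rng = np.random.default_rng(0)
        shuffled = LabeledDataset(data.samples,
                                  rng.permutation(data.labels), data.blocks)
        acc = blockwise_cv(shuffled, KnnConfig(k=1)).mean_accuracy
        assert acc == pytest.approx(0.2, abs=0.05)

    def test_mahalanobis_refit_per_fold(self, small_world):
        _, data = small_world
        res = blockwise_cv(data, KnnConfig(k=1, metric="mahalanobis"))
        assert 0.0 <= res.mean_accuracy <= 1.0

    def test_reduced_cv_matches_full_within_two_points(self, small_world):
        """Reduction runs on each fold's training split individually;
        on separable data DSM-kNN tracks full kNN."""
        _, data = small_world
        full = blockwise_cv(data, KnnConfig(k=1)).mean_accuracy
        red = blockwise_cv(data, KnnConfig(k=1),
                           reduction=ReductionConfig(m_prototypes=6,
                                                     iterations=10,
                                                     seed=0)).mean_accuracy
        assert red >= full - 0.02

    def test_noise_monotone_degradation(self):
        accs = []
        for sd in (0.05, 0.6, 1.5):
            cfg = SyntheticConfig(classes=("rs", "pw", "fl"), noise_sd=sd,
                                  repetitions=3, samples_per_rep=40, seed=5)
            accs.append(blockwise_cv(generate_envelope_dataset(cfg),
                                     KnnConfig(k=1)).mean_accuracy)
        assert accs[1] <= accs[0] + 0.02
        assert accs[2] <= accs[1] + 0.02

    def test_single_block_rejected(self):
        data = LabeledDataset(np.ones((4, 8)), np.array(["a"] * 4),
                              np.zeros(4))
        with pytest.raises(ValueError, match="2 blocks"):
            blockwise_cv(data, KnnConfig(k=1))


class TestGridSearch:
    def test_single_cell_grid(self, small_world):
        _, data = small_world
        best, table = grid_search(data, ks=[3], metrics=["manhattan"],
                                  weightings=["uniform"])
        assert best.config == KnnConfig(k=3, metric="manhattan",
                                        weighting="uniform")
        assert set(table.columns) == {"k", "k_rel", "metric", "weighting",
                                      "fold", "accuracy"}

    def test_tie_breaks_to_smallest_k_then_euclidean(self, small_world):
        _, data = small_world  # perfectly separable: every cell scores 1.0
        best, _ = grid_search(data, ks=[5, 1, 3],
                              metrics=["chebyshev", "euclidean"],
                              weightings=["1/d^2"])
        assert best.config.k == 1
        assert best.config.metric == "euclidean"

    def test_anisotropic_noise_prefers_mahalanobis(self):
        """Classes separated along one channel, drowned by noise on
        another: the covariance-whitening metric must win the grid."""
        rng = np.random.default_rng(1)
        n = 240
        x = rng.normal(0, 0.25, size=(n, 8))
        labels = np.array(["a", "b"] * (n // 2))
        x[labels == "b", 0] += 1.0      # signal channel
        x[:, 1] *= 24.0                  # pure-noise channel dominates
        data = LabeledDataset(np.abs(x), labels, np.arange(n) % 4)
        best, table = grid_search(data, ks=[5],
                                  metrics=["euclidean", "mahalanobis"],
                                  weightings=["uniform"])
        assert best.config.metric == "mahalanobis"
        by_metric = table.groupby("metric")["accuracy"].mean()
        assert by_metric["mahalanobis"] > by_metric["euclidean"]

    def test_empty_grid_rejected(self, small_world):
        _, data = small_world
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(data, ks=[])


class TestRidge:
    def test_shrinkage_limit(self, rng):
        x = rng.normal(size=(50, 8))
        labels = rng.choice(["a", "b"], size=50)
        small = rr_fit(x, labels, lam=1e12)
        assert np.abs(small.weights).max() < 1e-6

    def test_zero_penalty_interpolates_square_design(self, rng):
        x = rng.normal(size=(8, 8))  # full-rank square design, no intercept
        labels = np.array(list("aabbccdd"))
        model = rr_fit(x, labels, lam=0.0, fit_intercept=False)
        _, _, act = rr_predict(model, x)
        targets = (labels[:, None] == model.classes[None, :]).astype(float)
        np.testing.assert_allclose(act, targets, atol=1e-8)

    def test_recovers_linear_classes(self, rng):
        x = rng.uniform(0, 1, size=(300, 8))
        labels = np.where(x[:, 0] + x[:, 1] > x[:, 2] + x[:, 3], "a", "b")
        model = rr_fit(x, labels, lam=1e-3)
        pred, _, _ = rr_predict(model, x)
        assert np.mean(pred == labels) > 0.95

    def test_sklearn_oracle(self, rng):
        x = rng.normal(size=(100, 8))
        labels = rng.choice(["a", "b", "c"], size=100)
        ours = rr_fit(x, labels, lam=2.0, fit_intercept=False)
        y = (labels[:, None] == ours.classes[None, :]).astype(float)
        sk = Ridge(alpha=2.0, fit_intercept=False).fit(x, y)
        np.testing.assert_allclose(ours.weights, sk.coef_.T, atol=1e-8)

    def test_intensity_scaled_targets(self, rng):
        x = np.vstack([np.ones(8), 0.5 * np.ones(8)])
        model = rr_fit(np.tile(x, (20, 1)),
                       np.array(["a", "a"] * 20),
                       intensities=np.array([1.0, 0.5] * 20), lam=1e-6,
                       fit_intercept=False)
        _, scales, _ = rr_predict(model, x)
        np.testing.assert_allclose(scales, [1.0, 0.5], atol=1e-3)


class TestRff:
    def test_bounded_by_sqrt_two_over_d(self, rng):
        z = rff_map(rng.normal(size=(100, 8)), d_features=64, sigma=1.0,
                    seed=3)
        assert np.abs(z).max() <= np.sqrt(2 / 64) + 1e-12

    def test_seed_determinism(self, rng):
        x = rng.normal(size=(10, 8))
        np.testing.assert_array_equal(rff_map(x, 32, 1.0, seed=5),
                                      rff_map(x, 32, 1.0, seed=5))

    def test_kernel_approximation(self, rng):
        """<z(x), z(y)> -> exp(-||x-y||^2 / 2 sigma^2) within the
        O(1/sqrt(D)) Monte-Carlo band."""
        sigma, d_features = 1.5, 4096
        x, y = rng.normal(size=(2, 8))
        zx = rff_map(x, d_features, sigma, seed=0)[0]
        zy = rff_map(y, d_features, sigma, seed=0)[0]
        kernel = np.exp(-np.sum((x - y) ** 2) / (2 * sigma ** 2))
        assert zx @ zy == pytest.approx(kernel,
                                        abs=3 / np.sqrt(d_features))

    def test_rr_rff_classifies_separable(self, small_world):
        _, data = small_world
        model = rr_rff_fit(data.samples, data.labels, seed=0)
        pred, _, _ = rr_rff_predict(model, data.samples)
        assert np.mean(pred == data.labels) > 0.9

    def test_median_heuristic_positive(self, rng):
        assert median_heuristic(rng.normal(size=(50, 8))) > 0
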