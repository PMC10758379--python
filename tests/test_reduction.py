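"""DSM/LVQ3 prototype generation: initialization, updates, determinism."""

import numpy as np
import pytest

from myoknn import (KnnConfig, KnnModel, LabeledDataset, OpCounter,
                    PrototypeSet, ReductionConfig, count_operations,
                    dsm_step, initialize_prototypes, knn_classify_batch,
                    lvq3_step, reduce)


def _dataset(samples, labels, blocks=None):
    samples = np.asarray(samples, dtype=float)
    if blocks is None:
        blocks = np.arange(len(samples))
    return LabeledDataset(samples, np.array(labels), np.asarray(blocks))


def _two_cluster_world(rng, n_per=40, sep=10.0, sd=0.2):
    """Two classes far apart relative to their spread, two blocks each."""
    a = rng.normal(0.0, sd, size=(n_per, 8)) + 1.0
    b = rng.normal(0.0, sd, size=(n_per, 8)) + 1.0
    b[:, :4] += sep
    samples = np.vstack([np.abs(a), np.abs(b)])
    labels = np.array(["a"] * n_per + ["b"] * n_per)
    blocks = np.r_[np.arange(n_per) % 2, 2 + np.arange(n_per) % 2]
    return _dataset(samples, labels, blocks)


def _protos(vectors, labels):
    return PrototypeSet(np.array(vectors, dtype=float), np.array(labels))


class TestInitialize:
    def test_m_equals_c_gives_exact_centroids(self, small_world):
        _, data = small_world
        protos = initialize_prototypes(data, m=4, seed=0)
        assert len(protos) == 4
        for cls in data.classes:
            centroid = data.samples[data.labels == cls].mean(axis=0)
            np.testing.assert_allclose(
                protos.prototypes[protos.labels == cls][0], centroid)

    def test_random_fill_round_robin(self, world6000):
        """5 classes, M = 7: centroids plus 2 draws from distinct classes."""
        _, data = world6000
        protos = initialize_prototypes(data, m=7, seed=1)
        assert len(protos) == 7
        counts = {c: int(np.sum(protos.labels == c)) for c in data.classes}
        assert sorted(counts.values()) == [1, 1, 1, 2, 2]

    def test_seed_determinism(self, small_world):
        _, data = small_world
        p1 = initialize_prototypes(data, m=9, seed=11)
        p2 = initialize_prototypes(data, m=9, seed=11)
        np.testing.assert_array_equal(p1.prototypes, p2.prototypes)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_m_below_class_count_rejected(self, small_world):
        _, data = small_world
        with pytest.raises(ValueError, match="m_prototypes"):
            initialize_prototypes(data, m=2, seed=0)

    def test_small_class_samples_with_replacement(self):
        data = _dataset([np.zeros(8), np.ones(8)], ["a", "b"])
        with pytest.warns(RuntimeWarning, match="replacement"):
            protos = initialize_prototypes(data, m=8, seed=0)
        assert len(protos) == 8


class TestDsmStep:
    def test_agreeing_nearest_changes_nothing(self):
        protos = _protos([0.2 * np.ones(8), np.ones(8)], ["b", "a"])
        before = protos.prototypes.copy()
        dsm_step(protos, 0.4 * np.ones(8), "b", alpha=0.01)
        np.testing.assert_array_equal(protos.prototypes, before)

    def test_penalize_and_reward(self):
        """Wrong nearest 0.2*1 is pushed to 0.198*1 (p <- p - a(x-p));
        the nearest same-label prototype is pulled toward x."""
        protos = _protos([0.2 * np.ones(8), 0.9 * np.ones(8)], ["a", "b"])
        dsm_step(protos, 0.4 * np.ones(8), "b", alpha=0.01)
        np.testing.assert_allclose(protos.prototypes[0], 0.198 * np.ones(8))
        np.testing.assert_allclose(protos.prototypes[1], 0.895 * np.ones(8))

    def test_reward_formula(self):
        protos = _protos([0.35 * np.ones(8), 0.2 * np.ones(8)], ["a", "b"])
        dsm_step(protos, 0.4 * np.ones(8), "b", alpha=0.01)
        # nearest (0.35, 'a') penalized; same-label (0.2, 'b') rewarded
        np.testing.assert_allclose(protos.prototypes[1], 0.202 * np.ones(8))

    def test_no_same_label_prototype_only_penalizes(self):
        protos = _protos([0.2 * np.ones(8)], ["a"])
        dsm_step(protos, 0.4 * np.ones(8), "b", alpha=0.01)
        np.testing.assert_allclose(protos.prototypes[0], 0.198 * np.ones(8))


class TestLvq3Step:
    def test_outside_window_unchanged(self):
        protos = _protos([np.zeros(8), np.ones(8)], ["a", "b"])
        before = protos.prototypes.copy()
        lvq3_step(protos, 0.05 * np.ones(8), "b", alpha=0.01, window=0.3)
        np.testing.assert_array_equal(protos.prototypes, before)

    def test_mixed_labels_inside_window(self):
        protos = _protos([np.zeros(8), np.ones(8)], ["b", "a"])
        x = 0.45 * np.ones(8)  # d0/d1 = 0.45/0.55 > (1-w)/(1+w) = 0.538
        lvq3_step(protos, x, "b", alpha=0.01, window=0.3)
        np.testing.assert_allclose(protos.prototypes[0],
                                   0.01 * 0.45 * np.ones(8))  # rewarded
        np.testing.assert_allclose(protos.prototypes[1],
                                   (1 + 0.01 * 0.55) * np.ones(8))  # penalized

    def test_both_same_label_rewarded_damped(self):
        protos = _protos([np.zeros(8), np.ones(8)], ["b", "b"])
        lvq3_step(protos, 0.45 * np.ones(8), "b", alpha=0.01, epsilon=0.1)
        np.testing.assert_allclose(protos.prototypes[0],
                                   0.001 * 0.45 * np.ones(8))
        np.testing.assert_allclose(protos.prototypes[1],
                                   (1 - 0.001 * 0.55) * np.ones(8))

    def test_neither_matching_inside_window_unchanged(self):
        protos = _protos([np.zeros(8), np.ones(8)], ["a", "c"])
        before = protos.prototypes.copy()
        lvq3_step(protos, 0.45 * np.ones(8), "b", alpha=0.01)
        np.testing.assert_array_equal(protos.prototypes, before)


class TestReduce:
    @pytest.mark.parametrize("method", ["dsm", "lvq3"])
    def test_output_size_is_exactly_m(self, method, rng):
        for trial in range(10):
            data = _two_cluster_world(np.random.default_rng(trial))
            cfg = ReductionConfig(method=method, m_prototypes=5,
                                  iterations=3, seed=trial,
                                  shuffle=bool(trial % 2))
            assert len(reduce(data, cfg)) == 5

    def test_zero_iterations_returns_initialization(self, small_world):
        _, data = small_world
        cfg = ReductionConfig(m_prototypes=6, iterations=0, seed=4)
        protos = reduce(data, cfg)
        init = initialize_prototypes(data, m=6, seed=4)
        np.testing.assert_array_equal(protos.prototypes, init.prototypes)

    def test_separable_two_class_perfect_heldout(self, rng):
        """Inter-class distance >> intra-class spread: 1-NN on the 2
        generated prototypes classifies a held-out block perfectly."""
        data = _two_cluster_world(rng)
        train = data.subset(data.blocks % 2 == 0)
        test = data.subset(data.blocks % 2 == 1)
        protos = reduce(train, ReductionConfig(m_prototypes=2,
                                               iterations=20, seed=0))
        model = KnnModel.fit(protos.to_dataset(), KnnConfig(k=1))
        assert np.mean(knn_classify_batch(model, test.samples)
                       == test.labels) == 1.0

    def test_order_robustness(self, rng):
        """Held-out accuracy moves < 2 points when the pass order is
        shuffled (each step depends only on the previous state)."""
        data = _two_cluster_world(rng, sd=0.8, sep=4.0)
        train = data.subset(data.blocks % 2 == 0)
        test = data.subset(data.blocks % 2 == 1)
        accs = []
        for shuffle in (False, True):
            cfg = ReductionConfig(m_prototypes=4, iterations=10, seed=9,
                                  shuffle=shuffle)
            model = KnnModel.fit(reduce(train, cfg).to_dataset(),
                                 KnnConfig(k=1))
            accs.append(np.mean(knn_classify_batch(model, test.samples)
                                == test.labels))
        assert abs(accs[0] - accs[1]) < 0.02

    def test_prototypes_stay_bounded(self, rng):
        data = _two_cluster_world(rng)
        protos = reduce(data, ReductionConfig(m_prototypes=4, iterations=30,
                                              seed=2))
        limit = 2 * np.abs(data.samples).max()
        assert np.abs(protos.prototypes).max() <= limit


class TestOperationCounts:
    def test_reduction_distance_evals_exact(self, rng):
        data = _two_cluster_world(rng, n_per=30)  # N = 60
        cfg = ReductionConfig(m_prototypes=4, iterations=5, seed=0)
        counter = OpCounter()
        reduce(data, cfg, counter=counter)
        assert counter.distance_evals == 5 * 60 * 4
        assert count_operations(60, 4, 2, 5)["reduction_distance_evals"] \
            == counter.distance_evals

    def test_doubling_n_doubles_count(self):
        rng = np.random.default_rng(0)
        counts = []
        for n_per in (30, 60):
            data = _two_cluster_world(rng, n_per=n_per)
            counter = OpCounter()
            reduce(data, ReductionConfig(m_prototypes=4, iterations=5,
                                         seed=0), counter=counter)
            counts.append(counter.distance_evals)
        assert counts[1] == 2 * counts[0]

    def test_initialization_needs_no_distances(self):
        assert count_operations(100, 7, 5, 40)["init_distance_evals"] == 0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            count_operations(10, 2, 5, 1)  # m < c
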