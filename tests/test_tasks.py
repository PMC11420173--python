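"""P-networks, supervised tasks, controls and the IDX container."""

import numpy as np
import pytest

from genebottle import _mlp
from genebottle.tasks import (DenseLayer, PNetSpec, TaskDataset, build_pnet,
                              cifar10_pnet_spec, count_pnet_parameters,
                              evaluate, load_idx, load_idx_dataset,
                              make_synthetic_task, mnist_pnet_spec, save_idx,
                              shuffle_weights, train_pnet)


class TestParameterCounts:
    def test_dense_classifier_total(self):
        assert count_pnet_parameters(mnist_pnet_spec()) == 636_010

    def test_conv_classifier_total(self):
        assert count_pnet_parameters(cifar10_pnet_spec()) == 1_369_738

    def test_tiny_and_empty(self):
        assert count_pnet_parameters(PNetSpec((DenseLayer(2, 3),))) == 9
        assert count_pnet_parameters(PNetSpec(())) == 0

    def test_inconsistent_chain_rejected(self):
        with pytest.raises(ValueError):
            PNetSpec((DenseLayer(4, 8), DenseLayer(9, 2)))


class TestBuild:
    def test_seeded_reproducibility(self):
        spec = mnist_pnet_spec(4, 8, 3)
        a, b = build_pnet(spec, seed=1), build_pnet(spec, seed=1)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])
        c = build_pnet(spec, seed=2)
        assert any(not np.array_equal(a.params[n], c.params[n])
                   for n in a.params)

    def test_standard_shapes(self):
        p = build_pnet(mnist_pnet_spec(), seed=0)
        assert p.params["layer0.W"].shape == (784, 800)
        assert p.params["layer0.b"].shape == (800,)
        assert p.params["layer1.W"].shape == (800, 10)
        assert p.params["layer1.b"].shape == (10,)


@pytest.fixture(scope="module")
def small_task():
    return make_synthetic_task(n_classes=4, image_side=8, n_train=400,
                               n_test=200, noise_sd=0.3, seed=5)


class TestTraining:
    def test_budget_accounting(self, small_task):
        """Updates × minibatch size covers the image budget (± final batch)."""
        train, _ = small_task
        counted = []

        class CountingSGD(_mlp.SGDMomentum):
            def step(self, layers, grads):
                counted.append(1)
                return super().step(layers, grads)

        p = build_pnet(mnist_pnet_spec(8, 8, 4), seed=0)
        budget = 333
        train_pnet(p, train, budget, batch_size=32, seed=1,
                   optimizer=CountingSGD(0.05, 0.9))
        n_updates = len(counted)
        assert (n_updates - 1) * 32 < budget <= n_updates * 32

    def test_zero_learning_rate_inert(self, small_task):
        train, test = small_task
        p = build_pnet(mnist_pnet_spec(8, 8, 4), seed=2)
        before = evaluate(p, test)
        train_pnet(p, train, 400, lr=0.0, momentum=0.0, seed=3)
        assert evaluate(p, test) == before

    def test_separable_task_learnable(self):
        """A linearly separable (margin > 0) 2-class task is mastered
        within 5 epochs."""
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(600, 16))
        margin = np.abs(X[:, 0] + X[:, 1] - 1.0) > 0.15
        X = X[margin][:300]
        y = (X[:, 0] + X[:, 1] > 1.0).astype(int)
        ds = TaskDataset(X, y)
        p = build_pnet(mnist_pnet_spec(4, 16, 2), seed=8)
        for e in range(5):
            train_pnet(p, ds, image_budget=len(ds), batch_size=32, seed=9 + e)
        assert evaluate(p, ds) >= 0.95

    def test_empty_dataset_error(self):
        p = build_pnet(mnist_pnet_spec(4, 4, 2), seed=0)
        empty = TaskDataset(np.zeros((0, 16)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            train_pnet(p, empty, 10)
        with pytest.raises(ValueError):
            evaluate(p, empty)


class TestEvaluate:
    def test_chance_on_shuffled_labels(self, small_task):
        """Any net scores ~1/n_classes once labels carry no information."""
        _, test = small_task
        rng = np.random.default_rng(11)
        scrambled = TaskDataset(test.inputs,
                                rng.permutation(test.labels), "test")
        p = build_pnet(mnist_pnet_spec(8, 8, 4), seed=12)
        acc = evaluate(p, scrambled)
        se = np.sqrt(0.25 * 0.75 / len(scrambled))
        assert abs(acc - 0.25) <= 3 * se + 1e-9

    def test_single_example(self, small_task):
        _, test = small_task
        one = TaskDataset(test.inputs[:1], test.labels[:1], "test")
        p = build_pnet(mnist_pnet_spec(8, 8, 4), seed=13)
        assert evaluate(p, one) in (0.0, 1.0)

    def test_all_zero_net_constant_output(self, small_task):
        """Zero parameters → equal logits → argmax tie-break to class 0, so
        accuracy equals class-0 frequency exactly."""
        _, test = small_task
        p = build_pnet(mnist_pnet_spec(8, 8, 4), seed=14)
        for name in p.params:
            p.params[name] = np.zeros_like(p.params[name])
        assert evaluate(p, test) == float(np.mean(test.labels == 0))

    def test_deterministic(self, small_task):
        _, test = small_task
        p = build_pnet(mnist_pnet_spec(8, 8, 4), seed=15)
        assert evaluate(p, test) == evaluate(p, test)


class TestShuffle:
    def test_value_multiset_preserved(self, small_task):
        p = build_pnet(mnist_pnet_spec(8, 8, 4), seed=16)
        q = shuffle_weights(p, seed=17)
        for name in p.params:
            np.testing.assert_array_equal(np.sort(p.params[name].ravel()),
                                          np.sort(q.params[name].ravel()))

    def test_shuffle_actually_permutes(self, small_task):
        p = build_pnet(mnist_pnet_spec(8, 8, 4), seed=18)
        q = shuffle_weights(p, seed=19)
        assert not np.array_equal(p.params["layer0.W"], q.params["layer0.W"])


class TestSyntheticTask:
    def test_noiseless_nearest_prototype_perfect(self):
        train, test = make_synthetic_task(n_classes=4, image_side=8,
                                          n_train=40, n_test=40,
                                          noise_sd=0.0, seed=20)
        protos = np.stack([train.inputs[train.labels == c][0]
                           for c in range(4)])
        d = ((test.inputs[:, None] - protos[None]) ** 2).sum(axis=(2, 3))
        assert np.mean(np.argmin(d, axis=1) == test.labels) == 1.0

    def test_balanced_labels(self):
        train, test = make_synthetic_task(n_classes=5, image_side=6,
                                          n_train=500, n_test=250, seed=21)
        for ds in (train, test):
            counts = np.bincount(ds.labels, minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_learnable_at_moderate_noise(self):
        train, test = make_synthetic_task(n_classes=4, image_side=8,
                                          n_train=600, n_test=300,
                                          noise_sd=0.3, seed=22)
        p = build_pnet(mnist_pnet_spec(8, 16, 4), seed=23)
        for _ in range(6):
            train_pnet(p, train, image_budget=600, seed=24)
        assert evaluate(p, test) >= 0.9

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            make_synthetic_task(n_classes=1)
        with pytest.raises(ValueError):
            make_synthetic_task(n_train=2, n_classes=10)


class TestIdx:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(25)
        images = rng.integers(0, 256, size=(7, 5, 5), dtype=np.uint8)
        path = tmp_path / "imgs.idx"
        save_idx(path, images)
        np.testing.assert_array_equal(load_idx(path), images)

    def test_dataset_scaling(self, tmp_path):
        images = np.full((3, 4, 4), 255, dtype=np.uint8)
        labels = np.array([0, 1, 2], dtype=np.uint8)
        save_idx(tmp_path / "x.idx", images)
        save_idx(tmp_path / "y.idx", labels)
        ds = load_idx_dataset(tmp_path / "x.idx", tmp_path / "y.idx")
        assert ds.inputs.max() == 1.0 and len(ds) == 3

    def test_bad_magic(self, tmp_path):
        path = tmp_path / "bad.idx"
        path.write_bytes(b"\x01\x02\x03\x04rest")
        with pytest.raises(ValueError, match="magic"):
            load_idx(path)

    def test_truncated_payload(self, tmp_path):
        path = tmp_path / "trunc.idx"
        import struct
        path.write_bytes(struct.pack(">BBBBII", 0, 0, 0x08, 2, 10, 10) + b"\x00" * 5)
        with pytest.raises(ValueError, match="payload"):
            load_idx(path)
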