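"""The nested loop: annealing, blending, reproducibility, transfer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genebottle.genomes import build_dense_genome
from genebottle.model import GenomicBottleneck
from genebottle.tasks import (TaskDataset, build_pnet, evaluate,
                              mnist_pnet_spec, train_pnet)
from genebottle.training import (IntermittentConfig, anneal_coefficient,
                                 blend_weights, generate_pnet_weights,
                                 intermittent_train, transfer_init, zero_shot)

from conftest import IMAGE_BUDGET, MASTER_SEED, OUTER_ITERATIONS, TASK_SEED


class TestAnnealing:
    @pytest.mark.parametrize("n,lam,expected", [
        (0, 20, 1.0),
        (20, 20, math.exp(-1.0)),
    ])
    def test_values(self, n, lam, expected):
        assert anneal_coefficient(n, lam) == pytest.approx(expected, rel=1e-12)

    def test_late_iterations_negligible(self):
        assert anneal_coefficient(460, 20) < 1e-9

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            anneal_coefficient(5, 0.0)
        with pytest.raises(ValueError):
            anneal_coefficient(-1, 20.0)

    @settings(derandomize=True, deadline=None)
    @given(st.integers(1, 400), st.floats(0.5, 100.0))
    def test_strictly_decreasing_in_bounds(self, n, lam):
        e0, e1 = anneal_coefficient(n - 1, lam), anneal_coefficient(n, lam)
        assert 0.0 < e1 < e0 <= 1.0


class TestBlending:
    def test_endpoints_exact(self):
        W = {"a": np.array([[2.0, -1.0]])}
        What = {"a": np.array([[0.5, 3.0]])}
        np.testing.assert_array_equal(blend_weights(W, What, 1.0)["a"], W["a"])
        np.testing.assert_array_equal(blend_weights(W, What, 0.0)["a"], What["a"])

    def test_midpoint(self):
        W = {"a": np.array([2.0])}
        What = {"a": np.array([0.0])}
        assert blend_weights(W, What, 0.5)["a"][0] == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            blend_weights({"a": np.zeros(2)}, {"a": np.zeros(3)}, 0.5)

    @settings(derandomize=True, deadline=None)
    @given(st.floats(0.0, 1.0))
    def test_contraction_toward_genome(self, eps):
        """‖W_next − Ŵ‖ = ε‖W_prev − Ŵ‖ exactly, by linearity."""
        rng = np.random.default_rng(0)
        W = {"a": rng.standard_normal((3, 3))}
        What = {"a": rng.standard_normal((3, 3))}
        nxt = blend_weights(W, What, eps)
        lhs = np.linalg.norm(nxt["a"] - What["a"])
        rhs = eps * np.linalg.norm(W["a"] - What["a"])
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


def _tiny_setup(task_seed=TASK_SEED):
    model = GenomicBottleneck.from_synthetic(
        weight_hidden=(10, 5), n_classes=4, image_side=8, n_hidden=8,
        n_train=300, n_test=200, noise_sd=0.4, seed=task_seed)
    return model


class TestIntermittentLoop:
    def test_reproducible_history(self):
        cfg = IntermittentConfig(outer_iterations=6, image_budget=600,
                                 master_seed=5)
        runs = []
        for _ in range(2):
            m = _tiny_setup()
            _, h = intermittent_train(m.pnet_spec, m.genome.copy(),
                                      m.train_ds, m.test_ds, cfg)
            runs.append(h)
        for col in runs[0].columns:
            np.testing.assert_allclose(runs[0][col], runs[1][col], atol=1e-6)

    def test_genome_size_constant(self):
        m = _tiny_setup()
        size0 = m.genome.genome_size
        cfg = IntermittentConfig(outer_iterations=3, image_budget=300,
                                 master_seed=6)
        genome, _ = intermittent_train(m.pnet_spec, m.genome, m.train_ds,
                                       m.test_ds, cfg)
        assert genome.genome_size == size0

    def test_coverage_validated_before_training(self):
        m = _tiny_setup()
        del m.genome.entries["layer0.W"]
        cfg = IntermittentConfig(outer_iterations=2, image_budget=100)
        with pytest.raises(ValueError, match="layer0.W"):
            intermittent_train(m.pnet_spec, m.genome, m.train_ds, m.test_ds, cfg)

    def test_history_epsilon_schedule(self):
        m = _tiny_setup()
        cfg = IntermittentConfig(outer_iterations=4, image_budget=300,
                                 lam=2.0, master_seed=7)
        _, h = intermittent_train(m.pnet_spec, m.genome, m.train_ds,
                                  m.test_ds, cfg)
        assert h.epsilon.iloc[0] == 1.0
        np.testing.assert_allclose(
            h.epsilon.iloc[1:], [math.exp(-n / 2.0) for n in (1, 2, 3)])


class TestZeroShot:
    def test_untrained_genome_at_chance(self):
        m = _tiny_setup()
        acc = zero_shot(m.genome, m.pnet_spec, m.test_ds)
        se = np.sqrt(0.25 * 0.75 / len(m.test_ds))
        assert abs(acc - 0.25) <= 3 * se + 1e-9

    def test_equals_explicit_generation(self, default_run):
        model = default_run.model
        params = generate_pnet_weights(default_run.genome, model.pnet_spec)
        explicit = evaluate(build_pnet(model.pnet_spec, params=params),
                            model.test_ds)
        assert zero_shot(default_run.genome, model.pnet_spec,
                         model.test_ds) == explicit

    def test_no_annealing_with_recovery_budget(self):
        """Pure re-initialisation (λ=0) still reaches above-chance innate
        performance when the inner budget allows full recovery from the
        genome decode each generation."""
        m = GenomicBottleneck.from_synthetic(seed=TASK_SEED)
        res = m.fit(outer_iterations=100, image_budget=6000, lam=0.0,
                    master_seed=MASTER_SEED)
        assert res.zero_shot_accuracy >= 0.5  # 5× chance


class TestTransferInit:
    def test_full_subset_equals_generation(self, default_run):
        model = default_run.model
        p = transfer_init(default_run.genome, [0, 1], model.pnet_spec, seed=3)
        gen = generate_pnet_weights(default_run.genome, model.pnet_spec)
        for name in gen:
            np.testing.assert_array_equal(p.params[name], gen[name])

    def test_empty_subset_equals_random_build(self, default_run):
        model = default_run.model
        p = transfer_init(default_run.genome, [], model.pnet_spec, seed=3)
        q = build_pnet(model.pnet_spec, seed=3)
        for name in q.params:
            np.testing.assert_array_equal(p.params[name], q.params[name])

    def test_invalid_subset(self, default_run):
        with pytest.raises(ValueError):
            transfer_init(default_run.genome, [5], default_run.model.pnet_spec)

    def test_low_layer_transfer_speeds_related_task(self, default_run):
        """Transferring the input layer from a trained genome reaches a fixed
        accuracy on a relabeled sibling task in fewer epochs than random
        init — the low-level features generalise."""
        model = default_run.model
        perm = np.roll(np.arange(10), 3)
        train2 = TaskDataset(model.train_ds.inputs,
                             perm[model.train_ds.labels], "train")
        test2 = TaskDataset(model.test_ds.inputs,
                            perm[model.test_ds.labels], "test")

        def epochs_to(pnet, thresh=0.85, max_epochs=12):
            rng = np.random.default_rng(42)
            for e in range(1, max_epochs + 1):
                train_pnet(pnet, train2, image_budget=len(train2),
                           seed=rng.integers(2**31))
                if evaluate(pnet, test2) >= thresh:
                    return e
            return max_epochs + 1

        warm = epochs_to(transfer_init(default_run.genome, [0],
                                       model.pnet_spec, seed=100))
        cold = epochs_to(build_pnet(model.pnet_spec, seed=100))
        assert warm < cold
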