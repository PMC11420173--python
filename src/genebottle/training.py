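"""Intermittent (nested-loop) training of genomes.

The outer loop plays the role of evolution, the inner loop the role of
learning: each generation the p-network is (re)built from the genome, trained
on the task for a fixed image budget, and the g-networks are then regressed
onto the trained weights. Early generations are protected from naive genomes
by weight annealing — the p-network starts each generation from the convex
blend W = ε·W_prev + (1−ε)·Ŵ with ε(n) = exp(−n/λ), so the raw genome only
takes over once it has something to say.

Zero-shot (innate) performance is the test accuracy of a p-network decoded
from the genome with no task training at all; the history logs it every
generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import _mlp
from .gnet import GenomeEnsemble, fit_gnet, generate_pnet_weights
from .labeling import weight_example_arrays
from .tasks import PNet, PNetSpec, TaskDataset, build_pnet, evaluate, train_pnet

__all__ = ["AnnealSchedule", "IntermittentConfig", "anneal_coefficient",
           "blend_weights", "intermittent_train", "zero_shot", "transfer_init"]


def anneal_coefficient(n: int, lam: float) -> float:
    """ε(n) = exp(−n/λ): 1 at the first generation, → 0 as the genome matures."""
    if lam <= 0:
        raise ValueError(f"annealing constant must be positive, got {lam}")
    if n < 0:
        raise ValueError(f"iteration index must be non-negative, got {n}")
    return math.exp(-n / lam)


@dataclass
class AnnealSchedule:
    """Iterator view of the annealing coefficient."""

    lam: float
    n: int = 0

    def current(self) -> float:
        return anneal_coefficient(self.n, self.lam)

    def advance(self) -> float:
        eps = self.current()
        self.n += 1
        return eps


def blend_weights(W_prev: Dict[str, np.ndarray],
                  W_hat_prev: Dict[str, np.ndarray],
                  eps: float) -> Dict[str, np.ndarray]:
    """Elementwise convex combination ε·W_prev + (1−ε)·Ŵ, per tensor
    (weights and biases alike)."""
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"blend coefficient {eps} outside [0, 1]")
    out = {}
    for name, W in W_prev.items():
        What = W_hat_prev[name]
        if W.shape != What.shape:
            raise ValueError(
                f"shape mismatch for {name}: {W.shape} vs {What.shape}")
        out[name] = eps * W + (1.0 - eps) * What
    return out


@dataclass
class IntermittentConfig:
    """Hyperparameters of the nested loop.

    Defaults follow the full-scale recipe: 500 outer iterations, a
    10,000-image inner budget, SGD-momentum for the p-network and Adam for
    the g-networks. Weight g-nets train ``gnet_epochs`` (2) epochs with
    minibatch ``gnet_batch_size`` (100); bias g-nets — tiny tensors needing
    a finer recipe — train ``gnet_bias_epochs`` (10) epochs with minibatch
    ``gnet_bias_batch_size`` (10). ``gnet_sample_sizes`` maps tensor names
    to per-iteration sample counts (e.g. 1e5 / 1e4 / 1e4 for the dense
    input-weight / output-weight / hidden-bias tensors at full scale);
    unlisted tensors are enumerated exhaustively. ``lam`` is the annealing
    constant in iterations; 0 disables annealing (every generation
    re-initialises the p-network directly from the genome decode).
    """

    outer_iterations: int = 500
    image_budget: int = 10_000
    gnet_sample_sizes: Optional[Dict[str, int]] = None
    gnet_epochs: int = 2
    gnet_bias_epochs: int = 10
    pnet_lr: float = 0.05
    pnet_momentum: float = 0.9
    pnet_batch_size: int = 128
    gnet_lr: float = 1e-3
    gnet_batch_size: int = 100
    gnet_bias_batch_size: int = 10
    lam: float = 20.0
    master_seed: int = 0

    def __post_init__(self):
        if self.outer_iterations < 1 or self.image_budget < 1 or self.gnet_epochs < 0:
            raise ValueError("iteration counts and budgets must be positive")
        if self.lam < 0:
            raise ValueError("lam must be >= 0 (0 disables annealing)")


def _epsilon(n: int, lam: float) -> float:
    if n == 0:
        return 1.0  # the naive genome never overwrites the initial p-network
    return anneal_coefficient(n, lam) if lam > 0 else 0.0


def intermittent_train(pnet_spec: PNetSpec, genome: GenomeEnsemble,
                       train_ds: TaskDataset, test_ds: TaskDataset,
                       config: IntermittentConfig,
                       callback=None):
    """Run the nested loop; returns (genome, history DataFrame).

    Per outer iteration n: (1) start the p-network from the annealed blend of
    last generation's trained weights and the genome's decode (generation 0
    starts from a random net); (2) train it on the task for the configured
    image budget; (3) regress every compressed tensor's g-network onto the
    trained weights from a seeded uniform sample of entries; (4) copy raw
    tensors verbatim into the genome; log the genome's zero-shot accuracy.
    The genome's g-networks and their Adam state persist across iterations.
    Fully reproducible from ``config.master_seed``.
    """
    shapes = pnet_spec.parameter_shapes()
    missing = [n for n in shapes if n not in genome.entries]
    if missing:
        raise ValueError(f"genome does not cover tensors: {missing}")
    for name, entry in genome.compressed_items():
        size = int(np.prod(shapes[name]))
        want = (config.gnet_sample_sizes or {}).get(name)
        if want is not None and want < 1:
            raise ValueError(f"sample size for {name} must be positive")

    ss = np.random.SeedSequence(config.master_seed)
    init_seed, train_seed, sample_seed, gfit_seed = ss.spawn(4)
    train_rng = np.random.default_rng(train_seed)
    sample_rng = np.random.default_rng(sample_seed)
    gfit_rng = np.random.default_rng(gfit_seed)

    pnet = build_pnet(pnet_spec, seed=init_seed)
    W_prev = {k: v.copy() for k, v in pnet.params.items()}
    optimizers = {name: _mlp.Adam(lr=config.gnet_lr)
                  for name, _ in genome.compressed_items()}
    genome_size0 = genome.genome_size

    rows = []
    for n in range(config.outer_iterations):
        eps = _epsilon(n, config.lam)
        W_hat = generate_pnet_weights(genome, pnet_spec)
        pnet = build_pnet(pnet_spec, params=blend_weights(W_prev, W_hat, eps))
        pnet = train_pnet(pnet, train_ds, config.image_budget,
                          lr=config.pnet_lr, momentum=config.pnet_momentum,
                          batch_size=config.pnet_batch_size,
                          seed=train_rng.integers(2**31))
        W_prev = {k: v.copy() for k, v in pnet.params.items()}

        losses = {}
        for name, entry in genome.compressed_items():
            tensor = pnet.params[name]
            size = tensor.size
            want = (config.gnet_sample_sizes or {}).get(name)
            sample = None if want is None else min(want, size)
            X, y = weight_example_arrays(tensor, entry.scheme, sample,
                                         sample_rng.integers(2**31))
            # bias vectors are tiny and get the longer/finer fitting recipe
            is_bias = tensor.ndim == 1
            losses[name] = fit_gnet(
                entry.gnet, (X, y),
                epochs=config.gnet_bias_epochs if is_bias else config.gnet_epochs,
                optimizer=optimizers[name],
                batch_size=(config.gnet_bias_batch_size if is_bias
                            else config.gnet_batch_size),
                seed=gfit_rng.integers(2**31))
        for name, entry in genome.entries.items():
            if not hasattr(entry, "gnet"):
                entry.values = pnet.params[name].copy()

        zs = zero_shot(genome, pnet_spec, test_ds)
        assert genome.genome_size == genome_size0, "genome size drifted"
        row = {"iteration": n, "epsilon": eps, "zero_shot_accuracy": zs,
               "trained_accuracy": evaluate(pnet, test_ds)}
        row.update({f"gnet_loss[{k}]": v for k, v in losses.items()})
        rows.append(row)
        if callback is not None:
            callback(n, row, genome)
    return genome, pd.DataFrame(rows)


def zero_shot(genome: GenomeEnsemble, pnet_spec: PNetSpec,
              test_ds: TaskDataset) -> float:
    """Innate accuracy: decode the genome into a p-network and evaluate it
    with no task training. Empirical surrogate of the innate error term."""
    params = generate_pnet_weights(genome, pnet_spec)
    return evaluate(build_pnet(pnet_spec, params=params), test_ds)


def transfer_init(genome: GenomeEnsemble, layer_subset: Sequence[int],
                  pnet_spec: PNetSpec, seed=None) -> PNet:
    """P-network with the listed layers decoded from the genome and all
    other layers freshly randomly initialised under ``seed``."""
    n_layers = len([l for l in pnet_spec.trainable_layers()])
    bad = [k for k in layer_subset if not 0 <= k < n_layers]
    if bad:
        raise ValueError(f"layer subset {bad} outside 0..{n_layers - 1}")
    covered = set()
    for k in layer_subset:
        for suffix in ("W", "b"):
            name = f"layer{k}.{suffix}"
            if name in pnet_spec.parameter_shapes() and name not in genome.entries:
                raise ValueError(f"genome does not cover transferred tensor {name}")
    pnet = build_pnet(pnet_spec, seed=seed)
    decoded = generate_pnet_weights(genome)
    for k in layer_subset:
        for suffix in ("W", "b"):
            name = f"layer{k}.{suffix}"
            if name in pnet.params:
                pnet.params[name] = decoded[name]
    return pnet
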