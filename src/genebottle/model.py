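"""Model/Results facade over the nested-loop machinery.

:class:`GenomicBottleneck` bundles a p-network architecture, a genome and a
task; ``fit()`` runs intermittent training and returns a
:class:`BottleneckResults` carrying the trained genome, the per-iteration
history, the headline numbers (genome size, compression, zero-shot accuracy,
shuffled-weight control) and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genomes import build_dense_genome
from .gnet import GenomeEnsemble, compression_ratio, format_compression
from .tasks import (PNetSpec, TaskDataset, build_pnet, evaluate,
                    make_synthetic_task, mnist_pnet_spec, shuffle_weights)
from .training import (IntermittentConfig, generate_pnet_weights,
                       intermittent_train, zero_shot)

__all__ = ["GenomicBottleneck", "BottleneckResults"]


class GenomicBottleneck:
    """A genome/p-network/task triple, ready to co-train."""

    def __init__(self, pnet_spec: PNetSpec, genome: GenomeEnsemble,
                 train_ds: TaskDataset, test_ds: TaskDataset):
        self.pnet_spec = pnet_spec
        self.genome = genome
        self.train_ds = train_ds
        self.test_ds = test_ds

    @classmethod
    def from_synthetic(cls, weight_hidden: Sequence[int] = (30, 10),
                       n_classes: int = 10, image_side: int = 12,
                       n_hidden: int = 32, n_train: int = 2000,
                       n_test: int = 1000, noise_sd: float = 0.5,
                       seed: int = 0) -> "GenomicBottleneck":
        """Desk-scale instance on the synthetic noisy-prototype task."""
        train_ds, test_ds = make_synthetic_task(
            n_classes, image_side, n_train, n_test, noise_sd, seed=seed)
        spec = mnist_pnet_spec(image_side, n_hidden, n_classes)
        genome = build_dense_genome(spec, image_side, weight_hidden,
                                    bias_hidden=(5,), seed=seed)
        return cls(spec, genome, train_ds, test_ds)

    def fit(self, config: Optional[IntermittentConfig] = None,
            **config_overrides) -> "BottleneckResults":
        config = config or IntermittentConfig(**config_overrides)
        genome, history = intermittent_train(
            self.pnet_spec, self.genome, self.train_ds, self.test_ds, config)
        return BottleneckResults(self, genome, history, config)

    def zero_shot(self) -> float:
        return zero_shot(self.genome, self.pnet_spec, self.test_ds)


@dataclass
class BottleneckResults:
    model: GenomicBottleneck
    genome: GenomeEnsemble
    history: pd.DataFrame
    config: IntermittentConfig

    @property
    def genome_size(self) -> int:
        return self.genome.genome_size

    @property
    def pnet_size(self) -> int:
        return self.model.pnet_spec.n_parameters

    @property
    def compression(self) -> float:
        return compression_ratio(self.pnet_size, self.genome_size)

    @property
    def zero_shot_accuracy(self) -> float:
        return zero_shot(self.genome, self.model.pnet_spec, self.model.test_ds)

    def shuffled_control_accuracy(self, seed: int = 0) -> float:
        """Accuracy of the decoded p-network after within-tensor weight
        shuffling: chance if the genome encodes position-specific wiring."""
        params = generate_pnet_weights(self.genome, self.model.pnet_spec)
        pnet = build_pnet(self.model.pnet_spec, params=params)
        return evaluate(shuffle_weights(pnet, seed=seed), self.model.test_ds)

    def summary(self) -> str:
        chance = 1.0 / max(self.model.test_ds.n_classes, 1)
        lines = [
            "Genomic bottleneck — intermittent training results",
            "=" * 52,
            f"p-network parameters      {self.pnet_size:>12,}",
            f"genome size H(G)          {self.genome_size:>12,}",
            f"compression               {format_compression(self.compression):>12}",
            f"outer iterations          {self.config.outer_iterations:>12}",
            f"zero-shot accuracy        {self.zero_shot_accuracy:>12.4f}",
            f"shuffled-weight control   {self.shuffled_control_accuracy():>12.4f}",
            f"chance level              {chance:>12.4f}",
            f"final trained accuracy    {self.history['trained_accuracy'].iloc[-1]:>12.4f}",
        ]
        return "\n".join(lines)
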