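"""Experiment configuration: YAML round-trip and experiment runner.

A config file fully determines a run: the task (synthetic parameters or IDX
file paths), the p-network geometry, the genome's g-network widths, the
nested-loop hyperparameters and the master seed. ``run_experiment`` executes
intermittent training end-to-end and writes the genome checkpoint, the
history CSV and a plain-text report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .genomes import build_dense_genome
from .gnet import compression_ratio, format_compression
from .io import save_genome
from .model import BottleneckResults, GenomicBottleneck
from .tasks import load_idx_dataset, make_synthetic_task, mnist_pnet_spec
from .training import IntermittentConfig

__all__ = ["ExperimentConfig", "load_config", "save_config", "run_experiment"]


@dataclass
class ExperimentConfig:
    # task: synthetic generator parameters, or IDX paths overriding them
    n_classes: int = 10
    image_side: int = 12
    n_train: int = 2000
    n_test: int = 1000
    noise_sd: float = 0.5
    train_images: Optional[str] = None
    train_labels: Optional[str] = None
    test_images: Optional[str] = None
    test_labels: Optional[str] = None
    # p-network and genome
    n_hidden: int = 32
    weight_gnet_hidden: tuple = (30, 10)
    bias_gnet_hidden: tuple = (5,)
    # nested loop
    outer_iterations: int = 50
    image_budget: int = 2000
    gnet_epochs: int = 2
    lam: float = 20.0
    pnet_lr: float = 0.05
    gnet_lr: float = 1e-3
    master_seed: int = 0
    output_dir: str = "run_output"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weight_gnet_hidden"] = list(self.weight_gnet_hidden)
        d["bias_gnet_hidden"] = list(self.bias_gnet_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("weight_gnet_hidden", "bias_gnet_hidden"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))


def save_config(path, config: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def build_experiment(cfg: ExperimentConfig) -> GenomicBottleneck:
    if cfg.train_images:
        train_ds = load_idx_dataset(cfg.train_images, cfg.train_labels, "train")
        test_ds = load_idx_dataset(cfg.test_images, cfg.test_labels, "test")
    else:
        train_ds, test_ds = make_synthetic_task(
            cfg.n_classes, cfg.image_side, cfg.n_train, cfg.n_test,
            cfg.noise_sd, seed=cfg.master_seed)
    spec = mnist_pnet_spec(cfg.image_side, cfg.n_hidden, cfg.n_classes)
    genome = build_dense_genome(spec, cfg.image_side, cfg.weight_gnet_hidden,
                                cfg.bias_gnet_hidden, seed=cfg.master_seed)
    return GenomicBottleneck(spec, genome, train_ds, test_ds)


def run_experiment(config_path) -> BottleneckResults:
    """Validate, train, and write artifacts (genome.h5, history.csv,
    report.txt) to the configured output directory."""
    cfg = load_config(config_path)
    experiment = build_experiment(cfg)
    loop = IntermittentConfig(
        outer_iterations=cfg.outer_iterations, image_budget=cfg.image_budget,
        gnet_epochs=cfg.gnet_epochs, lam=cfg.lam, pnet_lr=cfg.pnet_lr,
        gnet_lr=cfg.gnet_lr, master_seed=cfg.master_seed)
    results = experiment.fit(loop)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_genome(out / "genome.h5", results.genome)
    results.history.to_csv(out / "history.csv", index=False)
    (out / "report.txt").write_text(results.summary() + "\n")
    return results
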