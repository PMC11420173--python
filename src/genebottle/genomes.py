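"""Genome builders and the standard accounting configurations.

``build_dense_genome`` wires a two-layer dense p-network to its genome: one
weight g-network per weight matrix, one bias g-network for the hidden biases,
and the output-class biases stored raw (a g-network for ten values would cost
more than the values themselves). ``dense_accounting`` / ``conv_accounting``
reproduce the printed genome-size tables for the standard dense (28×28, 800
hidden: genomes 613 / 1,353 / 1,973 against 636,010 p-parameters) and 9-layer
convolutional (genomes 3,798 / 9,378 / 14,958 against 1,369,738) classifiers.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .gnet import (CompressedTensor, GNet, GNetSpec, GenomeEnsemble, RawTensor,
                   compression_ratio, format_compression)
from .labeling import build_conv_scheme, build_dense_scheme
from .tasks import DenseLayer, PNetSpec, cifar10_pnet_spec, mnist_pnet_spec

__all__ = [
    "build_dense_genome", "dense_accounting", "conv_accounting",
    "DENSE_GNET_LADDER", "CONV_GNET_LADDER", "accounting_table",
]

# hidden-layer widths of the weight g-networks, by configuration name;
# the bias g-network is 10−5−1 in every dense configuration
DENSE_GNET_LADDER = {"GN5": (10, 5), "GN20": (20, 10), "GN30": (30, 10)}
CONV_GNET_LADDER = {"GN10": (10, 10), "GN30": (30, 10), "GN50": (50, 10)}


def build_dense_genome(pnet_spec: PNetSpec, image_side: int,
                       weight_hidden: Sequence[int] = (30, 10),
                       bias_hidden: Sequence[int] = (5,),
                       seed=None) -> GenomeEnsemble:
    """Genome ensemble covering a two-layer dense classifier.

    Pixel neurons are labelled Gray(x)+Gray(y), hidden units by plain binary
    index, classes by one-hot; weight g-nets read the 2-sided pair label,
    the hidden-bias g-net the hidden unit's own label, and class biases are
    raw-stored zeros. g-net hidden widths come from ``weight_hidden`` /
    ``bias_hidden`` (e.g. (30, 10) and (5,) give the GN30 configuration).
    """
    dense = [l for l in pnet_spec.layers if isinstance(l, DenseLayer)]
    if len(dense) != 2:
        raise ValueError("build_dense_genome expects a two-layer dense spec")
    n_hidden, n_classes = dense[0].out_units, dense[1].out_units
    if dense[0].in_units != image_side * image_side:
        raise ValueError(
            f"spec input {dense[0].in_units} != image {image_side}×{image_side}")
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    kw = dict(image_side=image_side, n_hidden=n_hidden, n_classes=n_classes)
    schemes = {
        "layer0.W": build_dense_scheme("image_input->hidden", **kw),
        "layer0.b": build_dense_scheme("hidden_bias", **kw),
        "layer1.W": build_dense_scheme("hidden->classes", **kw),
    }
    entries: Dict[str, object] = {}
    for k, (name, scheme) in enumerate(
            [("layer0.W", schemes["layer0.W"]), ("layer1.W", schemes["layer1.W"])]):
        spec = GNetSpec((scheme.total_width, *weight_hidden, 1))
        entries[name] = CompressedTensor(GNet(spec, seed=seeds[k]), scheme)
    bias_scheme = schemes["layer0.b"]
    bias_spec = GNetSpec((bias_scheme.total_width, *bias_hidden, 1))
    entries["layer0.b"] = CompressedTensor(GNet(bias_spec, seed=seeds[2]), bias_scheme)
    entries["layer1.b"] = RawTensor(np.zeros(n_classes))
    meta = {"weight_hidden": list(weight_hidden), "bias_hidden": list(bias_hidden),
            "image_side": image_side, "n_hidden": n_hidden, "n_classes": n_classes}
    return GenomeEnsemble(entries, meta)


def dense_accounting(name: str = "GN30", image_side: int = 28,
                     n_hidden: int = 800, n_classes: int = 10) -> dict:
    """Genome size, p-network size and compression for one dense configuration."""
    weight_hidden = DENSE_GNET_LADDER[name]
    pspec = mnist_pnet_spec(image_side, n_hidden, n_classes)
    genome = build_dense_genome(pspec, image_side, weight_hidden, (5,), seed=0)
    g = genome.genome_size
    p = pspec.n_parameters
    return {"name": name, "g_parameters": g, "p_parameters": p,
            "compression": compression_ratio(p, g),
            "compression_str": format_compression(compression_ratio(p, g))}


def conv_accounting(name: str = "GN30") -> dict:
    """Genome size, p-network size and compression for one 9-layer
    convolutional configuration.

    Each of the nine layers gets a 20-input weight g-network with biases on
    every layer, and an 8−10−1 bias g-network carrying only an output bias
    (91 parameters each); this convention reproduces all three printed genome
    totals. The layer-9 bias labels are the 10-bit class one-hot at decode
    time; the accounting convention for its bias net matches the other eight.
    """
    weight_hidden = CONV_GNET_LADDER[name]
    w_spec = GNetSpec((20, *weight_hidden, 1), bias_mode="all_layers")
    b_spec = GNetSpec((8, 10, 1), bias_mode="output_only")
    g = 9 * w_spec.n_parameters + 9 * b_spec.n_parameters
    p = cifar10_pnet_spec().n_parameters
    return {"name": name, "g_parameters": g, "p_parameters": p,
            "compression": compression_ratio(p, g),
            "compression_str": format_compression(compression_ratio(p, g))}


def accounting_table(family: str = "dense") -> list:
    """All rows of one accounting table (family 'dense' or 'conv')."""
    if family == "dense":
        return [dense_accounting(name) for name in DENSE_GNET_LADDER]
    if family == "conv":
        return [conv_accounting(name) for name in CONV_GNET_LADDER]
    raise ValueError(f"unknown family {family!r}")
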