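"""G-networks and genome ensembles.

A g-network is a small dense MLP that maps the binary pair label of a
(pre, post) neuron pair to one connection strength. The set of g-networks
(plus any raw-stored tensors) encoding an entire p-network is the *genome*;
its size — the total number of g-network parameters plus raw-stored values —
is the surrogate for genome entropy H(G), and p-network parameters divided by
genome size is the compression ratio.

Parameter-count conventions are explicit fields of :class:`GNetSpec`
(``bias_mode``): with ``all_layers`` every layer carries a bias vector; with
``output_only`` only the scalar output unit has a bias. The dense-classifier
genomes use ``all_layers`` throughout and store the few output-class biases
raw; the convolutional accounting uses ``all_layers`` weight nets and
``output_only`` bias nets. These conventions reproduce every printed genome
size (613 / 1,353 / 1,973 dense; 3,798 / 9,378 / 14,958 convolutional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Union

import numpy as np

from . import _mlp
from .labeling import LayerLabelScheme, BitLabel, weight_example_arrays

__all__ = [
    "GNetSpec", "GNet", "CompressedTensor", "RawTensor", "GenomeEnsemble",
    "count_parameters", "compression_ratio", "format_compression",
    "predict_weight", "generate_pnet_weights", "fit_gnet",
]


@dataclass(frozen=True)
class GNetSpec:
    """Structure of one g-network: layer widths (input … 1) and conventions.

    ``output_init_scale`` damps the output layer's random init so a freshly
    initialised g-network generates near-zero weights: a naive genome then
    decodes to a near-blank p-network rather than noise large enough to swamp
    the phenotype's weight scale (the standard output-scaled initialisation
    for weight-generating networks). It does not change the parameter count.
    """

    layer_widths: tuple
    hidden_activation: str = "relu"
    bias_mode: str = "all_layers"  # all_layers | output_only | none
    output_init_scale: float = 0.1

    def __post_init__(self):
        if len(self.layer_widths) < 2:
            raise ValueError("a g-network needs at least input and output layers")
        if self.layer_widths[-1] != 1:
            raise ValueError("g-network output width must be 1 (one weight)")
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")
        if self.bias_mode not in ("all_layers", "output_only", "none"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")

    @property
    def input_width(self) -> int:
        return self.layer_widths[0]

    @property
    def n_parameters(self) -> int:
        w = self.layer_widths
        weights = sum(w[k] * w[k + 1] for k in range(len(w) - 1))
        if self.bias_mode == "all_layers":
            return weights + sum(w[1:])
        if self.bias_mode == "output_only":
            return weights + 1
        return weights

    def bias_layers(self) -> list:
        n = len(self.layer_widths) - 1
        if self.bias_mode == "all_layers":
            return [True] * n
        if self.bias_mode == "output_only":
            return [False] * (n - 1) + [True]
        return [False] * n

    def to_dict(self) -> dict:
        return {"layer_widths": list(self.layer_widths),
                "hidden_activation": self.hidden_activation,
                "bias_mode": self.bias_mode,
                "output_init_scale": self.output_init_scale}

    @classmethod
    def from_dict(cls, d: dict) -> "GNetSpec":
        return cls(tuple(d["layer_widths"]), d["hidden_activation"],
                   d["bias_mode"], d.get("output_init_scale", 0.1))


class GNet:
    """A g-network with concrete parameters."""

    def __init__(self, spec: GNetSpec, seed=None, layers=None):
        self.spec = spec
        if layers is not None:
            self.layers = layers
        else:
            rng = np.random.default_rng(seed)
            self.layers = _mlp.init_layers(spec.layer_widths, rng,
                                           spec.bias_layers())
            W_out, b_out = self.layers[-1]
            self.layers[-1] = (W_out * spec.output_init_scale, b_out)

    @property
    def n_parameters(self) -> int:
        return self.spec.n_parameters

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Batch of labels (n, input_width) -> (n,) weights."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.spec.input_width:
            raise ValueError(
                f"label width {X.shape[1]} does not match g-network input "
                f"width {self.spec.input_width}")
        return _mlp.forward(self.layers, X, self.spec.hidden_activation).reshape(-1)

    def copy(self) -> "GNet":
        layers = [(W.copy(), None if b is None else b.copy())
                  for W, b in self.layers]
        return GNet(self.spec, layers=layers)


def predict_weight(gnet: GNet, pair_label) -> float:
    """Deterministic connection strength for one pair label."""
    if isinstance(pair_label, BitLabel):
        x = pair_label.as_array()
    else:
        x = np.asarray(pair_label, dtype=np.float64)
    return float(gnet.forward(x[None, :])[0])


@dataclass
class CompressedTensor:
    """A p-network tensor encoded by a (g-network, label scheme) pair."""

    gnet: GNet
    scheme: LayerLabelScheme

    def __post_init__(self):
        if self.scheme.total_width != self.gnet.spec.input_width:
            raise ValueError(
                f"scheme width {self.scheme.total_width} != g-network input "
                f"width {self.gnet.spec.input_width}")

    @property
    def genome_size(self) -> int:
        return self.gnet.n_parameters

    def generate(self) -> np.ndarray:
        flat = self.gnet.forward(self.scheme.all_labels())
        return flat.reshape(self.scheme.tensor_shape)


@dataclass
class RawTensor:
    """A tensor stored verbatim in the genome (cheaper than a g-network)."""

    values: np.ndarray

    @property
    def genome_size(self) -> int:
        return int(np.asarray(self.values).size)

    def generate(self) -> np.ndarray:
        return np.asarray(self.values).copy()


class GenomeEnsemble:
    """All g-networks (and raw tensors) encoding one p-network.

    ``entries`` maps tensor names (matching the p-network's parameter names)
    to :class:`CompressedTensor` or :class:`RawTensor`. ``metadata`` records
    the conventions needed to decode a checkpoint without the generating code.
    """

    def __init__(self, entries: Dict[str, Union[CompressedTensor, RawTensor]],
                 metadata: Optional[dict] = None):
        self.entries = dict(entries)
        self.metadata = dict(metadata or {})
        self.metadata.setdefault("bit_order", "msb_first")
        self.metadata.setdefault("concat_order", "pre_then_post")

    @property
    def genome_size(self) -> int:
        """H(G): g-network parameter counts plus raw-stored value counts."""
        return sum(e.genome_size for e in self.entries.values())

    def tensor_names(self):
        return list(self.entries)

    def compressed_items(self):
        return [(name, e) for name, e in self.entries.items()
                if isinstance(e, CompressedTensor)]

    def copy(self) -> "GenomeEnsemble":
        entries = {}
        for name, e in self.entries.items():
            if isinstance(e, CompressedTensor):
                entries[name] = CompressedTensor(e.gnet.copy(), e.scheme)
            else:
                entries[name] = RawTensor(e.values.copy())
        return GenomeEnsemble(entries, dict(self.metadata))


def count_parameters(obj) -> int:
    """Genome size of a GNetSpec, GNet, genome entry, ensemble, or an
    iterable of any of these. The empty ensemble counts 0."""
    if isinstance(obj, GNetSpec):
        return obj.n_parameters
    if isinstance(obj, GNet):
        return obj.n_parameters
    if isinstance(obj, (CompressedTensor, RawTensor)):
        return obj.genome_size
    if isinstance(obj, GenomeEnsemble):
        return obj.genome_size
    if isinstance(obj, dict):
        return sum(count_parameters(v) for v in obj.values())
    if isinstance(obj, Iterable):
        return sum(count_parameters(v) for v in obj)
    raise TypeError(f"cannot count parameters of {type(obj).__name__}")


def compression_ratio(p_count: int, g_count: int) -> float:
    """p-network parameters per genome parameter."""
    if g_count == 0:
        raise ZeroDivisionError("genome size is zero")
    return p_count / g_count


def format_compression(ratio: float) -> str:
    """Report a ratio the way the accounting tables print it: nearest integer
    (half away from zero), thousands separators, trailing ×."""
    import math
    rounded = int(math.floor(ratio + 0.5)) if ratio >= 0 else -int(math.floor(-ratio + 0.5))
    return f"{rounded:,}×"


def generate_pnet_weights(genome: GenomeEnsemble, spec=None) -> Dict[str, np.ndarray]:
    """Decode the genome into a full parameter set Ŵ.

    Compressed tensors come from g-network forward passes over their scheme's
    exhaustive label enumeration; raw tensors are copied verbatim. If a
    p-network ``spec`` is given, coverage and shapes are checked first.
    """
    if spec is not None:
        expected = spec.parameter_shapes()
        missing = [n for n in expected if n not in genome.entries]
        if missing:
            raise ValueError(f"genome does not cover tensors: {missing}")
    out = {}
    for name, entry in genome.entries.items():
        tensor = entry.generate()
        if spec is not None and name in spec.parameter_shapes():
            want = spec.parameter_shapes()[name]
            if tuple(tensor.shape) != tuple(want):
                raise ValueError(
                    f"generated {name} has shape {tensor.shape}, expected {want}")
        out[name] = tensor
    return out


def fit_gnet(gnet: GNet, examples, epochs: int = 2, *,
             optimizer: Optional[_mlp.Adam] = None, lr: float = 1e-3,
             batch_size: int = 100, seed=None, loss: str = "mse") -> float:
    """Train a g-network by stochastic gradient on the squared difference
    between its output and the target weights.

    ``examples`` is either an (X, y) array pair or an iterable of
    WeightExample records. The optimizer defaults to a fresh Adam; passing one
    in keeps moment state across calls (used by intermittent training).
    Returns the final epoch's mean loss. Zero epochs leaves parameters
    untouched and returns the current loss.
    """
    if isinstance(examples, tuple):
        X, y = examples
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
    else:
        records = list(examples)
        if not records:
            raise ValueError("empty example stream")
        X = np.stack([r.pair_label.as_array() for r in records])
        y = np.array([r.target_weight for r in records])
    if X.shape[0] == 0:
        raise ValueError("empty example stream")
    if loss == "mse":
        loss_fn = _mlp.mse_loss_grads
    elif loss == "l1":
        def loss_fn(layers, Xb, yb, hidden_activation):
            pred, cache = _mlp.forward(layers, Xb, hidden_activation,
                                       "identity", return_cache=True)
            resid = pred.reshape(-1) - yb.reshape(-1)
            delta = (np.sign(resid) / resid.size)[:, None]
            return float(np.mean(np.abs(resid))), _mlp._backprop(layers, cache, delta)
    else:
        raise ValueError(f"unknown loss {loss!r}")
    opt = optimizer if optimizer is not None else _mlp.Adam(lr=lr)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    final = float(loss_fn(gnet.layers, X, y, gnet.spec.hidden_activation)[0])
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            sel = order[start:start + batch_size]
            l, grads = loss_fn(gnet.layers, X[sel], y[sel],
                               gnet.spec.hidden_activation)
            gnet.layers = opt.step(gnet.layers, grads)
            losses.append(l)
        final = float(np.mean(losses))
    return final
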