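"""Phenotype networks and their supervised tasks.

The p-network is the task-performing classifier whose weights the genome
generates. Desk-scale work runs dense nets on synthetic image tasks (noisy
class prototypes); the standard 28×28 / 800-hidden digit classifier and the
9-layer all-convolutional architecture are available as specs for accounting
and, with user-supplied IDX files, full-scale runs. Dense nets (with dropout)
train and evaluate in-process; convolutional layers participate in parameter
accounting and label schemes only.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from . import _mlp

__all__ = [
    "DenseLayer", "ConvLayer", "DropoutLayer", "PNetSpec", "TaskDataset",
    "PNet", "count_pnet_parameters", "mnist_pnet_spec", "cifar10_pnet_spec",
    "build_pnet", "train_pnet", "evaluate", "shuffle_weights",
    "make_synthetic_task", "load_idx", "save_idx", "load_idx_dataset",
]


@dataclass(frozen=True)
class DenseLayer:
    in_units: int
    out_units: int
    activation: str = "relu"
    has_bias: bool = True

    @property
    def n_parameters(self) -> int:
        return self.in_units * self.out_units + (self.out_units if self.has_bias else 0)


@dataclass(frozen=True)
class ConvLayer:
    kernel: Tuple[int, int]
    in_filters: int
    out_filters: int
    stride: int = 1
    activation: str = "relu"
    has_bias: bool = True

    @property
    def n_parameters(self) -> int:
        kh, kw = self.kernel
        n = kh * kw * self.in_filters * self.out_filters
        return n + (self.out_filters if self.has_bias else 0)


@dataclass(frozen=True)
class DropoutLayer:
    probability: float

    @property
    def n_parameters(self) -> int:
        return 0


LayerDesc = Union[DenseLayer, ConvLayer, DropoutLayer]


@dataclass(frozen=True)
class PNetSpec:
    """Ordered layer descriptors of a phenotype network."""

    layers: tuple

    def __post_init__(self):
        prev_out = None
        for layer in self.layers:
            if isinstance(layer, DropoutLayer):
                continue
            if isinstance(layer, DenseLayer):
                fan_in, fan_out = layer.in_units, layer.out_units
            else:
                fan_in, fan_out = layer.in_filters, layer.out_filters
            if prev_out is not None and fan_in != prev_out:
                raise ValueError(
                    f"layer input {fan_in} does not chain from previous output {prev_out}")
            prev_out = fan_out

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.layers)

    def trainable_layers(self) -> list:
        return [l for l in self.layers if not isinstance(l, DropoutLayer)]

    def parameter_shapes(self) -> Dict[str, tuple]:
        """C-order shapes of every trainable tensor, keyed layerN.W / layerN.b."""
        shapes = {}
        idx = 0
        for layer in self.layers:
            if isinstance(layer, DropoutLayer):
                continue
            if isinstance(layer, DenseLayer):
                shapes[f"layer{idx}.W"] = (layer.in_units, layer.out_units)
                if layer.has_bias:
                    shapes[f"layer{idx}.b"] = (layer.out_units,)
            else:
                kh, kw = layer.kernel
                shapes[f"layer{idx}.W"] = (kh, kw, layer.in_filters, layer.out_filters)
                if layer.has_bias:
                    shapes[f"layer{idx}.b"] = (layer.out_filters,)
            idx += 1
        return shapes

    def is_dense(self) -> bool:
        return all(isinstance(l, (DenseLayer, DropoutLayer)) for l in self.layers)


def count_pnet_parameters(spec: PNetSpec) -> int:
    """Total weight and bias element count of the phenotype network."""
    return spec.n_parameters


def mnist_pnet_spec(image_side: int = 28, n_hidden: int = 800,
                    n_classes: int = 10) -> PNetSpec:
    """The two-layer dense digit classifier (784–800–10 by default;
    636,010 parameters)."""
    return PNetSpec((
        DenseLayer(image_side * image_side, n_hidden, "relu"),
        DenseLayer(n_hidden, n_classes, "identity"),
    ))


def cifar10_pnet_spec() -> PNetSpec:
    """The 9-layer all-convolutional classifier (1,369,738 parameters),
    with 50% dropout between layers 3 and 4."""
    return PNetSpec((
        ConvLayer((3, 3), 3, 96),
        ConvLayer((3, 3), 96, 96),
        ConvLayer((3, 3), 96, 96, stride=2),
        DropoutLayer(0.5),
        ConvLayer((3, 3), 96, 192),
        ConvLayer((3, 3), 192, 192),
        ConvLayer((3, 3), 192, 192, stride=2),
        ConvLayer((3, 3), 192, 192),
        ConvLayer((1, 1), 192, 192),
        ConvLayer((1, 1), 192, 10, activation="identity"),
    ))


@dataclass
class TaskDataset:
    """Supervised examples: inputs in [0, 1], integer class labels."""

    inputs: np.ndarray
    labels: np.ndarray
    split: str = "train"

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.inputs) != len(self.labels):
            raise ValueError("inputs and labels length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def flat_inputs(self) -> np.ndarray:
        return self.inputs.reshape(len(self.inputs), -1)


class PNet:
    """A dense phenotype network with concrete parameters."""

    def __init__(self, spec: PNetSpec, params: Dict[str, np.ndarray]):
        if not spec.is_dense():
            raise NotImplementedError(
                "in-process training/evaluation supports dense specs; "
                "convolutional specs are for accounting and label schemes")
        self.spec = spec
        self.params = params
        self._dense = [l for l in spec.layers if isinstance(l, DenseLayer)]
        # dropout probability applied after dense layer k
        self._dropout = [0.0] * len(self._dense)
        k = -1
        for layer in spec.layers:
            if isinstance(layer, DenseLayer):
                k += 1
            elif isinstance(layer, DropoutLayer) and k >= 0:
                self._dropout[k] = layer.probability

    def _layers(self) -> list:
        out = []
        for k in range(len(self._dense)):
            W = self.params[f"layer{k}.W"]
            b = self.params.get(f"layer{k}.b")
            out.append((W, b))
        return out

    def _store(self, layers: list) -> None:
        for k, (W, b) in enumerate(layers):
            self.params[f"layer{k}.W"] = W
            if b is not None:
                self.params[f"layer{k}.b"] = b

    def logits(self, X: np.ndarray, rng: Optional[np.random.Generator] = None
               ) -> np.ndarray:
        dropout = self._dropout if rng is not None else None
        return _mlp.forward(self._layers(), X, "relu", "identity",
                            dropout=dropout, rng=rng)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(X), axis=1)

    def copy(self) -> "PNet":
        return PNet(self.spec, {k: v.copy() for k, v in self.params.items()})


def build_pnet(spec: PNetSpec, seed=None,
               params: Optional[Dict[str, np.ndarray]] = None) -> PNet:
    """Fresh p-network with scaled-uniform (Glorot) random parameters under
    ``seed``, or with the given parameter set."""
    if params is not None:
        return PNet(spec, {k: np.asarray(v, dtype=np.float64).copy()
                           for k, v in params.items()})
    rng = np.random.default_rng(seed)
    params = {}
    idx = 0
    for layer in spec.layers:
        if isinstance(layer, DropoutLayer):
            continue
        if not isinstance(layer, DenseLayer):
            raise NotImplementedError("random init implemented for dense specs")
        params[f"layer{idx}.W"] = _mlp.glorot_uniform(rng, layer.in_units,
                                                      layer.out_units)
        if layer.has_bias:
            params[f"layer{idx}.b"] = np.zeros(layer.out_units)
        idx += 1
    return PNet(spec, params)


def train_pnet(pnet: PNet, dataset: TaskDataset, image_budget: int,
               lr: float = 0.05, momentum: float = 0.9, batch_size: int = 128,
               seed=None, optimizer: Optional[_mlp.SGDMomentum] = None) -> PNet:
    """Minibatch SGD (momentum) on softmax cross-entropy for exactly
    ``image_budget`` training images, sampled without replacement per pass.

    A budget of 10,000 on a 60,000-image set is one sixth of an epoch. Images
    are drawn uniformly without replacement; if the budget exceeds the set
    size the sampling restarts (epoch boundaries)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if image_budget < 1:
        raise ValueError("image budget must cover at least one image")
    rng = np.random.default_rng(seed)
    opt = optimizer if optimizer is not None else _mlp.SGDMomentum(lr, momentum)
    X = dataset.flat_inputs()
    y = dataset.labels
    layers = pnet._layers()
    remaining = image_budget
    while remaining > 0:
        take = min(remaining, len(dataset))
        order = rng.permutation(len(dataset))[:take]
        for start in range(0, take, batch_size):
            sel = order[start:start + batch_size]
            _, grads = _mlp.softmax_xent_grads(
                layers, X[sel], y[sel], "relu",
                dropout=pnet._dropout, rng=rng)
            layers = opt.step(layers, grads)
        remaining -= take
    pnet._store(layers)
    return pnet


def evaluate(pnet: PNet, dataset: TaskDataset) -> float:
    """Fraction of argmax-correct predictions; dropout disabled, so two
    evaluations of the same net agree exactly."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    preds = pnet.predict(dataset.flat_inputs())
    return float(np.mean(preds == dataset.labels))


def shuffle_weights(pnet: PNet, seed=None) -> PNet:
    """Control net: each tensor's entries randomly permuted in place, so the
    per-tensor weight distribution is preserved but all positional structure
    is destroyed. A genome that only learned a weight distribution would be
    unaffected; one that learned position-specific wiring drops to chance."""
    rng = np.random.default_rng(seed)
    params = {}
    for name, tensor in pnet.params.items():
        flat = tensor.reshape(-1).copy()
        rng.shuffle(flat)
        params[name] = flat.reshape(tensor.shape)
    return PNet(pnet.spec, params)


def make_synthetic_task(n_classes: int = 10, image_side: int = 12,
                        n_train: int = 2000, n_test: int = 1000,
                        noise_sd: float = 0.5, seed=0,
                        smoothness: float = 2.0) -> Tuple[TaskDataset, TaskDataset]:
    """Desk-scale stand-in for a handwritten-digit task.

    Each class gets a random smooth prototype image (low-pass filtered
    Gaussian field rescaled to [0, 1]); examples are the prototype plus iid
    Gaussian pixel noise, clipped back to [0, 1]. Classes are balanced and
    the train/test splits are disjoint by construction (independent draws).
    Everything is a deterministic function of ``seed``.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if image_side < 2 or n_train < n_classes or n_test < n_classes:
        raise ValueError("invalid task sizes")
    rng = np.random.default_rng(seed)
    protos = []
    for _ in range(n_classes):
        field = gaussian_filter(rng.standard_normal((image_side, image_side)),
                                sigma=smoothness)
        lo, hi = field.min(), field.max()
        protos.append((field - lo) / (hi - lo) if hi > lo else field * 0.0)
    protos = np.stack(protos)

    def draw(n: int, split: str) -> TaskDataset:
        labels = np.tile(np.arange(n_classes), int(np.ceil(n / n_classes)))[:n]
        rng.shuffle(labels)
        X = protos[labels] + noise_sd * rng.standard_normal(
            (n, image_side, image_side))
        return TaskDataset(np.clip(X, 0.0, 1.0), labels, split)

    return draw(n_train, "train"), draw(n_test, "test")


# ---------------------------------------------------------------------------
# IDX container (big-endian magic + dims header, raw byte payload)

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.dtype(">i2"),
               0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"), 0x0E: np.dtype(">f8")}


def load_idx(path) -> np.ndarray:
    """Read one IDX array file (the MNIST container dialect)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 4:
        raise ValueError(f"{path}: truncated IDX header at offset {len(data)}")
    zero, zero2, code, ndim = struct.unpack(">BBBB", data[:4])
    if zero != 0 or zero2 != 0 or code not in _IDX_DTYPES:
        raise ValueError(f"{path}: bad IDX magic {data[:4]!r} at offset 0")
    header_len = 4 + 4 * ndim
    if len(data) < header_len:
        raise ValueError(f"{path}: truncated IDX dimensions at offset {len(data)}")
    dims = struct.unpack(f">{ndim}I", data[4:header_len])
    dtype = np.dtype(_IDX_DTYPES[code])
    expected = int(np.prod(dims)) * dtype.itemsize
    payload = data[header_len:]
    if len(payload) != expected:
        raise ValueError(
            f"{path}: payload length {len(payload)} != header-declared "
            f"{expected} at offset {header_len}")
    return np.frombuffer(payload, dtype=dtype).reshape(dims)


def save_idx(path, array: np.ndarray) -> None:
    """Write an array as an IDX file (uint8 for images/labels, >f8 otherwise)."""
    array = np.asarray(array)
    if array.dtype == np.uint8:
        code, dtype = 0x08, np.uint8
    else:
        code, dtype = 0x0E, np.dtype(">f8")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, code, array.ndim))
        fh.write(struct.pack(f">{array.ndim}I", *array.shape))
        fh.write(np.ascontiguousarray(array, dtype=dtype).tobytes())


def load_idx_dataset(images_path, labels_path, split: str = "train") -> TaskDataset:
    """Pair of IDX files -> TaskDataset with pixel intensities scaled to [0, 1]."""
    images = load_idx(images_path).astype(np.float64)
    labels = load_idx(labels_path).astype(np.int64)
    if images.dtype != np.float64:
        images = images.astype(np.float64)
    if images.max(initial=0.0) > 1.0:
        images = images / 255.0
    if len(images) != len(labels):
        raise ValueError("image and label files disagree on example count")
    return TaskDataset(images, labels, split)
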