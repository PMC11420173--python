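"""Binary neuron labels and label schemes.

Every neuron of a phenotype network (p-network) carries a fixed-width binary
identity label — an abstraction of a molecular expression profile. A
connection between two neurons is addressed by the concatenation of the
presynaptic and postsynaptic labels; a generator network (g-network) maps that
pair label to a synaptic strength. This module defines the label codes (Gray,
plain binary, one-hot), the schemes that map every entry of a p-network weight
tensor to a unique pair label, and the enumeration of (label, weight) training
records for g-network regression.

Conventions (recorded in genome metadata so checkpoints are self-describing):
bits are most-significant first; the presynaptic label precedes the
postsynaptic one; indices are 0-based; within a label, image coordinates run
x before y and kernel coordinates before filter identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "BitLabel",
    "SegmentSpec",
    "LayerLabelScheme",
    "WeightExample",
    "gray_encode",
    "gray_decode",
    "binary_encode",
    "binary_decode",
    "one_hot_encode",
    "one_hot_decode",
    "build_dense_scheme",
    "build_conv_scheme",
    "enumerate_weight_examples",
]


@dataclass(frozen=True)
class BitLabel:
    """A fixed-width binary identity vector, most-significant bit first."""

    bits: tuple
    width: int

    def __post_init__(self):
        if len(self.bits) != self.width:
            raise ValueError(
                f"label has {len(self.bits)} bits but declared width {self.width}"
            )
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"label bits must be 0/1, got {self.bits}")

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    def concat(self, other: "BitLabel") -> "BitLabel":
        return BitLabel(self.bits + other.bits, self.width + other.width)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.float64)


def gray_encode(n: int, width: int) -> BitLabel:
    """Reflected-binary Gray code of ``n``, MSB first.

    Consecutive integers differ in exactly one bit, so neighbouring grid
    coordinates get nearby labels — the point of using Gray codes for pixel
    and kernel positions.
    """
    _check_range(n, width)
    g = n ^ (n >> 1)
    return _int_to_bits(g, width)


def gray_decode(label: BitLabel) -> int:
    g = _bits_to_int(label)
    n = 0
    while g:
        n ^= g
        g >>= 1
    return n


def binary_encode(n: int, width: int) -> BitLabel:
    """Standard base-2 encoding of ``n``, MSB first."""
    _check_range(n, width)
    return _int_to_bits(n, width)


def binary_decode(label: BitLabel) -> int:
    return _bits_to_int(label)


def one_hot_encode(k: int, width: int) -> BitLabel:
    """Label with exactly one bit set, at position ``k``."""
    if not 0 <= k < width:
        raise ValueError(f"one-hot index {k} out of range for width {width}")
    bits = [0] * width
    bits[k] = 1
    return BitLabel(tuple(bits), width)


def one_hot_decode(label: BitLabel) -> int:
    if sum(label.bits) != 1:
        raise ValueError(f"not a one-hot label: {label}")
    return label.bits.index(1)


def _check_range(n: int, width: int) -> None:
    if n < 0 or n >= (1 << width):
        raise ValueError(f"value {n} not representable in {width} bits")


def _int_to_bits(v: int, width: int) -> BitLabel:
    bits = tuple((v >> (width - 1 - k)) & 1 for k in range(width))
    return BitLabel(bits, width)


def _bits_to_int(label: BitLabel) -> int:
    v = 0
    for b in label.bits:
        v = (v << 1) | b
    return v


@dataclass(frozen=True)
class SegmentSpec:
    """One segment of a label: a code kind, its bit width and value range."""

    kind: str  # gray | binary | onehot
    width: int
    value_range: int

    def __post_init__(self):
        if self.kind not in ("gray", "binary", "onehot"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.width <= 0 or self.value_range <= 0:
            raise ValueError("width and value_range must be positive")
        if self.kind in ("gray", "binary") and (1 << self.width) < self.value_range:
            raise ValueError(
                f"{self.kind} segment of width {self.width} cannot encode "
                f"{self.value_range} values"
            )
        if self.kind == "onehot" and self.width != self.value_range:
            raise ValueError("one-hot segment width must equal its value range")

    def encode(self, value: int) -> BitLabel:
        if not 0 <= value < self.value_range:
            raise ValueError(
                f"value {value} outside segment range [0, {self.value_range})"
            )
        if self.kind == "gray":
            return gray_encode(value, self.width)
        if self.kind == "binary":
            return binary_encode(value, self.width)
        return one_hot_encode(value, self.width)

    def decode(self, label: BitLabel) -> int:
        if self.kind == "gray":
            return gray_decode(label)
        if self.kind == "binary":
            return binary_decode(label)
        return one_hot_decode(label)

    def encode_array(self, values: np.ndarray) -> np.ndarray:
        """Vectorised encoding: (n,) int array -> (n, width) float array."""
        values = np.asarray(values, dtype=np.int64)
        if values.min(initial=0) < 0 or values.max(initial=0) >= self.value_range:
            raise ValueError("values outside segment range")
        if self.kind == "onehot":
            out = np.zeros((values.size, self.width))
            out[np.arange(values.size), values] = 1.0
            return out
        v = values ^ (values >> 1) if self.kind == "gray" else values
        shifts = np.arange(self.width - 1, -1, -1)
        return ((v[:, None] >> shifts[None, :]) & 1).astype(np.float64)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "width": self.width,
                "value_range": self.value_range}

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentSpec":
        return cls(d["kind"], d["width"], d["value_range"])


@dataclass(frozen=True)
class LayerLabelScheme:
    """Maps every index of one p-network tensor to a unique pair label.

    ``pre_segments`` / ``post_segments`` describe the presynaptic and
    postsynaptic sides; ``pre_axes`` / ``post_axes`` say which tensor axes
    feed which segments (in segment order), so e.g. a flat 784-pixel axis can
    be split into (x, y) coordinate segments via ``pre_shape``. Bias tensors
    have no presynaptic side (``pre_segments`` empty).

    ``pre_shape`` is the multi-coordinate shape of the presynaptic index
    domain in *segment order*; the tensor's own axis is the C-order flattening
    of those coordinates in *spatial order* (``pre_spatial_order`` permutes
    segment order into C-order axes). For images the tensor axis is
    row-major ``y*side + x`` while segments run (x, y).
    """

    pre_segments: tuple
    post_segments: tuple
    tensor_shape: tuple
    pre_shape: tuple = ()
    post_shape: tuple = ()
    # permutation: position k holds the segment index supplying C-order axis k
    pre_spatial_order: tuple = ()
    post_spatial_order: tuple = ()

    def __post_init__(self):
        for name in ("pre", "post"):
            segs = getattr(self, f"{name}_segments")
            shape = getattr(self, f"{name}_shape")
            if not shape and segs:
                object.__setattr__(self, f"{name}_shape",
                                   tuple(s.value_range for s in segs))
                shape = getattr(self, f"{name}_shape")
            order = getattr(self, f"{name}_spatial_order")
            if not order and segs:
                object.__setattr__(self, f"{name}_spatial_order",
                                   tuple(range(len(segs))))
            if len(shape) != len(segs):
                raise ValueError(f"{name}_shape does not match segment count")
            for seg, extent in zip(segs, shape):
                if seg.value_range != extent:
                    raise ValueError(
                        f"{name} segment range {seg.value_range} != axis extent {extent}")
        n_covered = int(np.prod([s.value_range for s in
                                 self.pre_segments + self.post_segments]))
        n_tensor = int(np.prod(self.tensor_shape))
        if n_covered != n_tensor:
            raise ValueError(
                f"scheme covers {n_covered} labels but tensor has {n_tensor} entries")

    @property
    def pre_width(self) -> int:
        return sum(s.width for s in self.pre_segments)

    @property
    def post_width(self) -> int:
        return sum(s.width for s in self.post_segments)

    @property
    def total_width(self) -> int:
        return self.pre_width + self.post_width

    def _side_values(self, flat_idx: np.ndarray, name: str) -> np.ndarray:
        """(n,) flat side indices -> (n, n_segments) segment values."""
        shape = getattr(self, f"{name}_shape")
        order = getattr(self, f"{name}_spatial_order")
        if not shape:
            return np.zeros((flat_idx.size, 0), dtype=np.int64)
        spatial_shape = tuple(shape[k] for k in order)
        coords = np.unravel_index(flat_idx, spatial_shape)  # C order
        values = np.empty((flat_idx.size, len(shape)), dtype=np.int64)
        for axis_pos, seg_idx in enumerate(order):
            values[:, seg_idx] = coords[axis_pos]
        return values

    def labels_for_indices(self, flat_indices: np.ndarray) -> np.ndarray:
        """Vectorised pair labels: (n,) C-order tensor indices -> (n, total_width)."""
        flat_indices = np.asarray(flat_indices, dtype=np.int64)
        n_post = int(np.prod(self.post_shape)) if self.post_shape else 1
        pre_flat, post_flat = np.divmod(flat_indices, n_post)
        cols = []
        for name, flat in (("pre", pre_flat), ("post", post_flat)):
            values = self._side_values(flat, name)
            for k, seg in enumerate(getattr(self, f"{name}_segments")):
                cols.append(seg.encode_array(values[:, k]))
        if not cols:
            return np.zeros((flat_indices.size, 0))
        return np.concatenate(cols, axis=1)

    def all_labels(self) -> np.ndarray:
        """Pair labels for every tensor entry in C order: (n_entries, width)."""
        return self.labels_for_indices(np.arange(int(np.prod(self.tensor_shape))))

    def label_for_index(self, index: tuple) -> BitLabel:
        flat = int(np.ravel_multi_index(index, self.tensor_shape))
        row = self.labels_for_indices(np.array([flat]))[0]
        return BitLabel(tuple(int(b) for b in row), self.total_width)

    def index_for_label(self, label: BitLabel) -> tuple:
        """Invert a pair label back to its tensor index."""
        if label.width != self.total_width:
            raise ValueError("label width does not match scheme")
        pos = 0
        side_flat = {}
        for name in ("pre", "post"):
            segs = getattr(self, f"{name}_segments")
            shape = getattr(self, f"{name}_shape")
            order = getattr(self, f"{name}_spatial_order")
            values = []
            for seg in segs:
                chunk = BitLabel(label.bits[pos:pos + seg.width], seg.width)
                values.append(seg.decode(chunk))
                pos += seg.width
            if segs:
                spatial_shape = tuple(shape[k] for k in order)
                coords = tuple(values[k] for k in order)
                side_flat[name] = int(np.ravel_multi_index(coords, spatial_shape))
            else:
                side_flat[name] = 0
        n_post = int(np.prod(self.post_shape)) if self.post_shape else 1
        flat = side_flat["pre"] * n_post + side_flat["post"]
        return tuple(int(i) for i in np.unravel_index(flat, self.tensor_shape))

    def to_dict(self) -> dict:
        return {
            "pre_segments": [s.to_dict() for s in self.pre_segments],
            "post_segments": [s.to_dict() for s in self.post_segments],
            "tensor_shape": list(self.tensor_shape),
            "pre_shape": list(self.pre_shape),
            "post_shape": list(self.post_shape),
            "pre_spatial_order": list(self.pre_spatial_order),
            "post_spatial_order": list(self.post_spatial_order),
            "bit_order": "msb_first",
            "concat_order": "pre_then_post",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerLabelScheme":
        return cls(
            tuple(SegmentSpec.from_dict(s) for s in d["pre_segments"]),
            tuple(SegmentSpec.from_dict(s) for s in d["post_segments"]),
            tuple(d["tensor_shape"]),
            tuple(d.get("pre_shape", ())),
            tuple(d.get("post_shape", ())),
            tuple(d.get("pre_spatial_order", ())),
            tuple(d.get("post_spatial_order", ())),
        )


@dataclass(frozen=True)
class WeightExample:
    """One g-network regression record: a pair label and its target weight."""

    pair_label: BitLabel
    target_weight: float


def _bit_width(n_values: int) -> int:
    return max(1, int(np.ceil(np.log2(n_values))))


def build_dense_scheme(layer_role: str, *, image_side: int = 28,
                       n_hidden: int = 800, n_classes: int = 10,
                       coord_width: Optional[int] = None,
                       hidden_width: Optional[int] = None) -> Optional[LayerLabelScheme]:
    """Label scheme for one tensor of a two-layer dense classifier.

    Roles: ``image_input->hidden`` (weights pixel→hidden, Gray x/y pre label,
    binary hidden post label), ``hidden->classes`` (binary pre, one-hot post),
    ``hidden_bias`` (binary label only), ``class_bias`` (returns None: the
    handful of output biases is cheaper to store raw than to compress).

    Defaults reproduce the printed 28×28 / 800-hidden configuration, where
    every weight scheme yields 20-bit pair labels and the hidden-bias scheme
    a 10-bit label.
    """
    cw = coord_width if coord_width is not None else _bit_width(image_side)
    hw = hidden_width if hidden_width is not None else _bit_width(n_hidden)
    gray_xy = (SegmentSpec("gray", cw, image_side), SegmentSpec("gray", cw, image_side))
    hidden = SegmentSpec("binary", hw, n_hidden)
    classes = SegmentSpec("onehot", n_classes, n_classes)
    if layer_role == "image_input->hidden":
        return LayerLabelScheme(
            pre_segments=gray_xy, post_segments=(hidden,),
            tensor_shape=(image_side * image_side, n_hidden),
            pre_shape=(image_side, image_side),
            # tensor pixel axis is row-major y*side+x; segments run (x, y)
            pre_spatial_order=(1, 0),
        )
    if layer_role == "hidden->classes":
        return LayerLabelScheme(
            pre_segments=(hidden,), post_segments=(classes,),
            tensor_shape=(n_hidden, n_classes),
        )
    if layer_role == "hidden_bias":
        return LayerLabelScheme(
            pre_segments=(), post_segments=(hidden,), tensor_shape=(n_hidden,),
        )
    if layer_role == "class_bias":
        return None  # raw-stored
    raise ValueError(f"unknown dense layer role {layer_role!r}")


def build_conv_scheme(layer_index: int, *, kernel: tuple = (3, 3),
                      in_filters: int = 96, out_filters: int = 192,
                      n_classes: int = 10, bias: bool = False) -> LayerLabelScheme:
    """Label scheme for one layer of the 9-layer all-convolutional classifier.

    Layers 1–8: presynaptic label = Gray(kx, 2) + Gray(ky, 2) + binary
    in-filter (8 bits), postsynaptic = binary out-filter (8 bits) — 20 bits
    total. Layer 9: Gray widths shrink to 1+1 (1×1 kernel dummy coordinates)
    and the postsynaptic label is the 10-bit class one-hot. Bias schemes use
    only the postsynaptic label. Weight tensors are laid out
    (kh, kw, in_filters, out_filters).
    """
    if not 1 <= layer_index <= 9:
        raise ValueError(f"layer_index {layer_index} outside 1..9")
    if max(in_filters, out_filters) > 256:
        raise ValueError("filter counts above 256 are not representable in 8 bits")
    kh, kw = kernel
    gw = 1 if layer_index == 9 else 2
    if max(kh, kw) > (1 << gw):
        raise ValueError(f"kernel {kernel} not representable in {gw} Gray bits")
    out_seg = (SegmentSpec("onehot", n_classes, n_classes) if layer_index == 9
               else SegmentSpec("binary", 8, out_filters))
    if bias:
        n_out = n_classes if layer_index == 9 else out_filters
        return LayerLabelScheme(pre_segments=(), post_segments=(out_seg,),
                                tensor_shape=(n_out,))
    pre = (SegmentSpec("gray", gw, kw), SegmentSpec("gray", gw, kh),
           SegmentSpec("binary", 8, in_filters))
    return LayerLabelScheme(
        pre_segments=pre, post_segments=(out_seg,),
        tensor_shape=(kh, kw, in_filters, out_filters),
        pre_shape=(kw, kh, in_filters),
        # tensor C-order axes (kh, kw, in): segment order is (kx, ky, in)
        pre_spatial_order=(1, 0, 2),
    )


def enumerate_weight_examples(weight_tensor: np.ndarray,
                              scheme: LayerLabelScheme,
                              sample_size: Optional[int] = None,
                              seed: Optional[int] = None) -> Iterator[WeightExample]:
    """Yield (pair label, target weight) records for g-network regression.

    Without ``sample_size`` the enumeration is exhaustive in C order; with it,
    a uniform subset without replacement is drawn under ``seed``.
    """
    X, y = weight_example_arrays(weight_tensor, scheme, sample_size, seed)
    for row, w in zip(X, y):
        yield WeightExample(BitLabel(tuple(int(b) for b in row), scheme.total_width),
                            float(w))


def weight_example_arrays(weight_tensor: np.ndarray,
                          scheme: LayerLabelScheme,
                          sample_size: Optional[int] = None,
                          seed=None) -> tuple:
    """Vectorised form of :func:`enumerate_weight_examples`: (X, y) arrays."""
    weight_tensor = np.asarray(weight_tensor)
    if weight_tensor.shape != tuple(scheme.tensor_shape):
        raise ValueError(
            f"tensor shape {weight_tensor.shape} does not match scheme "
            f"{tuple(scheme.tensor_shape)}")
    n = weight_tensor.size
    if sample_size is None:
        idx = np.arange(n)
    else:
        if sample_size > n:
            raise ValueError(f"sample_size {sample_size} exceeds tensor size {n}")
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=sample_size, replace=False)
    return scheme.labels_for_indices(idx), weight_tensor.reshape(-1)[idx]
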