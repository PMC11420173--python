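"""Genome checkpoints: HDF5 parameter tensors + YAML metadata.

A checkpoint is decodable without the generating code: every g-network's
layer tensors are stored as datasets, and a YAML block in the file attributes
carries the label schemes, bias conventions, bit order and any run metadata.
Round-trips are lossless (float64 throughout).
"""

from __future__ import annotations

import json
from typing import Dict

import h5py
import numpy as np
import yaml

from .gnet import CompressedTensor, GNet, GNetSpec, GenomeEnsemble, RawTensor
from .labeling import LayerLabelScheme

__all__ = ["save_genome", "load_genome"]


def save_genome(path, genome: GenomeEnsemble) -> None:
    with h5py.File(path, "w") as fh:
        manifest = {"metadata": genome.metadata, "entries": {}}
        for name, entry in genome.entries.items():
            grp = fh.create_group(name)
            if isinstance(entry, CompressedTensor):
                manifest["entries"][name] = {
                    "kind": "compressed",
                    "gnet_spec": entry.gnet.spec.to_dict(),
                    "scheme": entry.scheme.to_dict(),
                }
                for k, (W, b) in enumerate(entry.gnet.layers):
                    grp.create_dataset(f"W{k}", data=W)
                    if b is not None:
                        grp.create_dataset(f"b{k}", data=b)
            else:
                manifest["entries"][name] = {"kind": "raw"}
                grp.create_dataset("values", data=entry.values)
        fh.attrs["manifest_yaml"] = yaml.safe_dump(_plain(manifest))


def load_genome(path) -> GenomeEnsemble:
    with h5py.File(path, "r") as fh:
        manifest = yaml.safe_load(fh.attrs["manifest_yaml"])
        entries: Dict[str, object] = {}
        for name, info in manifest["entries"].items():
            grp = fh[name]
            if info["kind"] == "compressed":
                spec = GNetSpec.from_dict(info["gnet_spec"])
                scheme = LayerLabelScheme.from_dict(info["scheme"])
                layers = []
                for k in range(len(spec.layer_widths) - 1):
                    W = np.asarray(grp[f"W{k}"])
                    b = np.asarray(grp[f"b{k}"]) if f"b{k}" in grp else None
                    layers.append((W, b))
                entries[name] = CompressedTensor(GNet(spec, layers=layers), scheme)
            else:
                entries[name] = RawTensor(np.asarray(grp["values"]))
    return GenomeEnsemble(entries, manifest.get("metadata", {}))


def _plain(obj):
    """Recursively convert numpy scalars/containers for clean YAML."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
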