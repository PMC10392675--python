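"""HDF5 container and text export for dataset bundles.

Layout: ``/tensors`` (N, T, D), ``/labels``, ``/ligand_ids``, ``/enantiomers``,
``/descriptor_names``, ``/units``, optional ``/split/{train_idx,val_idx}`` and
``/normalizer/{offset,scale}``; scalar metadata as root attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .data import DatasetBundle
from .featurize import Normalizer


def save_bundle(path, bundle: DatasetBundle, compress: bool = True):
    opts = {"compression": "gzip", "compression_opts": 4} if compress else {}
    with h5py.File(path, "w") as f:
        f.create_dataset("tensors", data=bundle.tensors.astype(np.float32), **opts)
        f.create_dataset("labels", data=bundle.labels)
        f.create_dataset("ligand_ids", data=bundle.ligand_ids)
        f.create_dataset(
            "enantiomers", data=np.char.encode(bundle.enantiomers.astype("U1"))
        )
        f.create_dataset(
            "descriptor_names",
            data=np.array([s.encode() for s in bundle.descriptor_names]),
        )
        f.create_dataset("units", data=np.array([s.encode() for s in bundle.units]))
        f.attrs["dt"] = bundle.dt
        f.attrs["meta"] = json.dumps(bundle.meta, default=str)
        if bundle.train_idx is not None:
            g = f.create_group("split")
            g.create_dataset("train_idx", data=bundle.train_idx)
            g.create_dataset("val_idx", data=bundle.val_idx)
        if bundle.normalizer is not None:
            g = f.create_group("normalizer")
            g.create_dataset("offset", data=bundle.normalizer.offset)
            g.create_dataset("scale", data=bundle.normalizer.scale)
            g.attrs["method"] = bundle.normalizer.method


def load_bundle(path) -> DatasetBundle:
    with h5py.File(path, "r") as f:
        bundle = DatasetBundle(
            tensors=f["tensors"][()],
            labels=f["labels"][()],
            ligand_ids=f["ligand_ids"][()],
            enantiomers=np.char.decode(f["enantiomers"][()]).astype("U1"),
            descriptor_names=[s.decode() for s in f["descriptor_names"][()]],
            units=[s.decode() for s in f["units"][()]],
            dt=float(f.attrs["dt"]),
            meta=json.loads(f.attrs.get("meta", "{}")),
        )
        if "split" in f:
            bundle.train_idx = f["split/train_idx"][()]
            bundle.val_idx = f["split/val_idx"][()]
        if "normalizer" in f:
            bundle.normalizer = Normalizer(
                offset=f["normalizer/offset"][()],
                scale=f["normalizer/scale"][()],
                method=f["normalizer"].attrs.get("method", "minmax"),
            )
    return bundle


def export_trajectory_csv(path, bundle: DatasetBundle, index: int):
    """One trajectory as frames x channels CSV with a descriptor-name header."""
    import pandas as pd

    pd.DataFrame(
        bundle.tensors[index], columns=bundle.descriptor_names
    ).to_csv(path, index_label="frame")


def write_split_manifest(path, bundle: DatasetBundle):
    """Columnar text: ligand_id <tab> split."""
    lines = ["ligand_id\tsplit"]
    train = set(bundle.ligand_ids[bundle.train_idx].tolist()) if bundle.train_idx is not None else set()
    for lig in np.unique(bundle.ligand_ids):
        lines.append(f"{int(lig)}\t{'train' if lig in train else 'validation'}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
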