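"""Loading and saving model inputs and run artifacts.

Two input routes: delimited text (participants x features table with a
header row of feature IDs and a leading participant-ID column, plus a
one-column phenotype file and an optional features x annotations table) or
a single HDF5 container with named datasets ``X``, ``Y``, ``Z``,
``feature_ids`` and ``annotation_names``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .prior_model import ModelData

__all__ = [
    "load_model_data_text",
    "load_model_data_hdf5",
    "save_model_data_hdf5",
    "write_manifest",
]


def load_model_data_text(
    features_path,
    phenotype_path,
    annotations_path=None,
    sep: str | None = None,
    validate: bool = True,
) -> ModelData:
    """Read delimited (comma/tab autodetected) feature/phenotype/annotation files."""
    kw = {"sep": sep} if sep else {"sep": None, "engine": "python"}
    feats = pd.read_csv(features_path, index_col=0, **kw)
    pheno = pd.read_csv(phenotype_path, index_col=0, **kw)
    y = pheno.iloc[:, 0].reindex(feats.index)
    if y.isna().any():
        raise ValueError("phenotype missing for some participants")
    Z = None
    annotation_names = None
    if annotations_path is not None:
        annot = pd.read_csv(annotations_path, index_col=0, **kw)
        annot = annot.reindex(feats.columns)
        if annot.isna().any().any():
            raise ValueError("annotation rows do not cover all features")
        Z = annot.to_numpy(dtype=float)
        annotation_names = list(annot.columns)
    return ModelData(
        X=feats.to_numpy(dtype=float),
        Y=y.to_numpy(dtype=float),
        Z=Z,
        feature_ids=list(feats.columns),
        annotation_names=annotation_names,
        validate=validate,
    )


def load_model_data_hdf5(path, validate: bool = True) -> ModelData:
    import h5py

    with h5py.File(path, "r") as f:
        fid = f["feature_ids"][()] if "feature_ids" in f else None
        names = f["annotation_names"][()] if "annotation_names" in f else None
        return ModelData(
            X=f["X"][()],
            Y=f["Y"][()],
            Z=f["Z"][()] if "Z" in f else None,
            feature_ids=[s.decode() for s in fid] if fid is not None else None,
            annotation_names=[s.decode() for s in names] if names is not None else None,
            validate=validate,
        )


def save_model_data_hdf5(data: ModelData, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=data.X)
        f.create_dataset("Y", data=data.Y)
        f.create_dataset("Z", data=data.Z)
        if data.feature_ids:
            f.create_dataset(
                "feature_ids", data=np.array(data.feature_ids, dtype="S")
            )
        if data.annotation_names:
            f.create_dataset(
                "annotation_names", data=np.array(data.annotation_names, dtype="S")
            )


def write_manifest(path, **entries) -> None:
    """Plain-text key-value run manifest (config, seeds, package version)."""
    from . import __version__

    lines = [f"brainvc_version = {__version__}"]
    lines += [f"{key} = {value}" for key, value in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")
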