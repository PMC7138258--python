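"""Volume and feature-store I/O.

Volumes are exchanged as NIfTI (voxel spacing in the affine); CI feature
sets go to HDF5 together with the CI config hash so that train/predict
feature-layout mismatches are detected rather than silently tolerated.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .grid import GridSpec


def write_volume(path, data: np.ndarray, grid: GridSpec,
                 meta: dict | None = None) -> None:
    affine = np.diag([grid.spacing_mm, grid.spacing_mm, grid.spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if meta:
        img.header["descrip"] = json.dumps(meta)[:79].encode()
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = float(img.affine[0, 0])
    dims = data.shape if data.ndim == 3 else (*data.shape, 1)
    return data, GridSpec(dims=tuple(int(d) for d in dims),
                          spacing_mm=spacing)


def write_manifest(path, manifest: list[dict]) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def save_features(path, features: np.ndarray, labels: np.ndarray,
                  roi: np.ndarray, ci_config_hash: str,
                  meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=np.asarray(features,
                                                     dtype=np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=labels)
        f.create_dataset("roi", data=np.asarray(roi, dtype=bool))
        f.attrs["ci_config_hash"] = ci_config_hash
        f.attrs["meta"] = json.dumps(meta or {})


def load_features(path, expected_hash: str | None = None):
    with h5py.File(path, "r") as f:
        chash = str(f.attrs["ci_config_hash"])
        if expected_hash is not None and chash != expected_hash:
            raise ValueError(
                f"CI config hash mismatch: store has {chash}, expected "
                f"{expected_hash}")
        return (f["features"][()], f["labels"][()], f["roi"][()], chash,
                json.loads(f.attrs["meta"]))
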