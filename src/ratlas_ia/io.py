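"""NIfTI and JSON I/O helpers.

World coordinates are RAS millimetres; voxel indices are 0-based; transforms
act in world space.  Volumes round-trip losslessly at the stored precision.
"""

from __future__ import annotations

import hashlib
import json
import os

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti", "save_json", "load_json", "config_hash"]


def save_nifti(data: np.ndarray, path: str | os.PathLike, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, os.fspath(path))


def load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(os.fspath(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def save_json(obj, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def load_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=_default).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
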