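"""NIfTI-1 round-trip plumbing via nibabel.

Intensity volumes are stored as float32, label maps and masks as unsigned
integers; round-trips preserve affines and voxel values (bit-exactly for
integer maps).  Non-finite data and malformed headers are refused with
explicit errors rather than propagated silently.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .image import Volume

__all__ = ["read_volume", "write_volume", "read_labels", "write_labels"]


def _load(path: str | Path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header/format errors
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    return img


def read_volume(path: str | Path) -> Volume:
    img = _load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if not np.isfinite(data).all():
        raise ValueError(f"{path} contains non-finite voxels")
    return Volume(data, np.asarray(img.affine))


def write_volume(vol: Volume, path: str | Path) -> Path:
    if not np.isfinite(vol.data).all():
        raise ValueError("refusing to write non-finite intensity data")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))
    return path


def read_labels(path: str | Path) -> Volume:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(np.asarray(data, dtype=float))
        if not np.isfinite(rounded).all():
            raise ValueError(f"{path}: label map contains non-finite values")
        data = rounded.astype(np.int64)
    return Volume(np.asarray(data), np.asarray(img.affine))


def write_labels(labels: Volume, path: str | Path) -> Path:
    data = labels.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError("label maps must be integer-valued")
    if data.min() < 0:
        raise ValueError("label maps must be non-negative")
    dtype = np.uint8 if data.max() < 256 else np.uint16 if data.max() < 65536 else np.uint32
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(data.astype(dtype), labels.affine)
    nib.save(img, str(path))
    return path
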