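"""NIfTI reading/writing for images and integer label maps (via nibabel)."""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .errors import FormatError
from .regions import LabelMap

__all__ = ["load_image", "save_image", "load_label_map", "save_label_map"]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    return aff


def load_image(path) -> tuple:
    """Load an intensity volume; returns ``(array, spacing_mm)``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:data.ndim])
    return data, spacing


def save_image(path, array: np.ndarray, spacing) -> None:
    array = np.asarray(array, dtype=np.float64)
    nib.save(nib.Nifti1Image(array, _affine(spacing)), str(path))


def load_label_map(path) -> LabelMap:
    """Load an integer label map; rejects non-integral voxel values."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise FormatError(f"{path}: label map holds non-integer values")
        data = data.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:data.ndim])
    return LabelMap(data, spacing)


def save_label_map(path, label_map: LabelMap) -> None:
    nib.save(nib.Nifti1Image(label_map.values.astype(np.int16),
                             _affine(label_map.spacing)), str(path))
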