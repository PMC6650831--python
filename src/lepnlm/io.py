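"""Reading and writing images: 8-bit PNG/TIFF slices and float32 NIfTI."""
from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .errors import InputError
from .phantom import quantize_uint8

_NII_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NII_SUFFIXES)


def read_image(path) -> np.ndarray:
    """Load an image as float64.

    PNG/TIFF are returned as 2-D (RGB collapsed to the channel mean);
    NIfTI volumes keep their trailing axes (processed slice-wise by the
    callers).
    """
    path = Path(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        return np.squeeze(data)
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise InputError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return arr


def write_image(path, arr) -> None:
    """Write float32 NIfTI or 8-bit PNG/TIFF depending on the suffix."""
    path = Path(path)
    arr = np.asarray(arr, dtype=np.float64)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4)), str(path))
        return
    iio.imwrite(path, quantize_uint8(arr))
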