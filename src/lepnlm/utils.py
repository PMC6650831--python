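"""Small shared helpers for image arrays.

Throughout the package a 2-D image is a plain ``numpy.ndarray`` of floats
(row, column indexing, 0-based), nominally on the 8-bit intensity scale
[0, 255] but never forcibly clipped except at export time.
"""
from __future__ import annotations

import numpy as np

from .errors import InputError


def as_image(arr, name: str = "image") -> np.ndarray:
    """Coerce to a 2-D float64 array, rejecting anything else."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2:
        raise InputError(f"{name} must be 2-D, got shape {a.shape}")
    if a.size == 0:
        raise InputError(f"{name} is empty")
    return a


def check_congruent(a: np.ndarray, b: np.ndarray, what: str = "images") -> None:
    if a.shape != b.shape:
        raise InputError(f"{what} must share a shape, got {a.shape} vs {b.shape}")
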