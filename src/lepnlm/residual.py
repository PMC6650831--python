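"""Method-noise detail recovery.

The method noise — noisy minus denoised — still carries image structure
that the main pass smoothed away. It is filtered with the same
feature-derived NLM weights as the main pass (the weights are a pure
function of the feature field and h, so reapplying them reproduces the
cached weights exactly), then smoothed with a 3x3 mean filter to suppress
what is left of the random component. The result is added back to the
denoised image.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .lepnet import FeatureField
from .nlm import NlmConfig, nlm_denoise_features
from .utils import as_image, check_congruent


@dataclass
class ResidualBundle:
    """Exact decomposition of one denoising run:
    ``method_noise = noisy - denoised`` and
    ``final = denoised + residual_details`` hold bitwise."""

    denoised: np.ndarray
    method_noise: np.ndarray
    residual_details: np.ndarray
    final: np.ndarray


def method_noise(noisy, denoised) -> np.ndarray:
    """Pixelwise difference between the noisy image and its denoised version."""
    a = as_image(noisy, "noisy")
    d = as_image(denoised, "denoised")
    check_congruent(a, d)
    return a - d


def recover_details(mnoise, F: FeatureField, cfg: NlmConfig) -> np.ndarray:
    """NLM-filter the method noise with the feature-derived weights, then
    apply a 3x3 reflect-padded mean filter."""
    filtered = nlm_denoise_features(mnoise, F, cfg)
    return ndimage.uniform_filter(filtered, size=3, mode="reflect")


def combine(denoised, details) -> np.ndarray:
    """Final image: denoised plus recovered details (no clipping here;
    clip only at 8-bit export)."""
    d = as_image(denoised, "denoised")
    r = as_image(details, "details")
    check_congruent(d, r)
    return d + r
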