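"""Single-image Rician noise estimation from the background.

Where the clean signal is zero, the Rician magnitude reduces to a Rayleigh
variate with E[A_noisy^2] = 2 sigma^2. The estimator segments the
background with Otsu's histogram threshold and solves that identity:

    sigma_hat = sqrt( mean(background pixel^2) / 2 ).

The estimator assumes the background is separable from tissue in the
intensity histogram; if dim tissue overlaps the Rayleigh mode the
below-threshold set is contaminated and sigma is overestimated. For
fields that are known background a priori, pass an explicit mask —
thresholding a pure-noise field would otherwise truncate the Rayleigh
distribution and bias the estimate low.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, InputError, UnreliableEstimateWarning
from .utils import as_image


@dataclass(frozen=True)
class NoiseEstimate:
    sigma_hat: float
    background_fraction: float
    threshold: float | None


def otsu_threshold(img) -> float:
    """Threshold maximizing between-class variance of a 256-bin histogram
    over the observed intensity range."""
    a = as_image(img)
    if a.min() == a.max():
        raise DegenerateInputError("constant image has no Otsu threshold")
    return float(threshold_otsu(a, nbins=256))


def estimate_sigma(noisy, background: np.ndarray | None = None) -> NoiseEstimate:
    """Estimate the Rician sigma of a magnitude image.

    Parameters
    ----------
    noisy : 2-D array
        Magnitude image.
    background : bool array, optional
        Pixels known to be pure background. When omitted, background is
        the set of pixels strictly below the Otsu threshold.
    """
    a = as_image(noisy, "noisy")
    if background is None:
        threshold = otsu_threshold(a)
        bg = a < threshold
    else:
        bg = np.asarray(background, dtype=bool)
        if bg.shape != a.shape:
            raise InputError("background mask must match the image shape")
        threshold = None
    frac = float(bg.mean())
    if frac == 0.0:
        raise InputError("no background pixels available for noise estimation")
    if frac < 0.01:
        warnings.warn(
            f"background covers only {frac:.2%} of the image; "
            "sigma estimate may be unreliable",
            UnreliableEstimateWarning,
            stacklevel=2,
        )
    sigma_hat = float(np.sqrt(np.mean(a[bg] ** 2) / 2.0))
    return NoiseEstimate(sigma_hat=sigma_hat, background_fraction=frac, threshold=threshold)
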