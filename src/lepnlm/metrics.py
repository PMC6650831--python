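"""PSNR and SSIM against an 8-bit peak of 255.

PSNR is 10*log10(255^2 / MSE) in dB (+inf for identical images). SSIM is
the standard luminance-contrast-structure product with stabilizers
c1 = (0.01*255)^2 and c2 = (0.03*255)^2, available in two window modes:

* ``global`` — single statistics over the whole image (the literal
  formula, handy for hand-verifiable toy cases);
* ``local`` — mean over sliding Gaussian windows (sigma 1.5, population
  covariance), the conventional reporting mode.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .errors import ConfigurationError
from .utils import as_image, check_congruent

_PEAK = 255.0
_C1 = (0.01 * _PEAK) ** 2
_C2 = (0.03 * _PEAK) ** 2


@dataclass(frozen=True)
class MetricsReport:
    psnr: float
    ssim: float
    image_id: str | None = None
    noise_level: float | None = None


def psnr(ref, test) -> float:
    a = as_image(ref, "ref")
    b = as_image(test, "test")
    check_congruent(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(_PEAK**2 / mse)


def ssim(ref, test, window_mode: str = "local") -> float:
    a = as_image(ref, "ref")
    b = as_image(test, "test")
    check_congruent(a, b)
    if window_mode == "global":
        mu_a, mu_b = a.mean(), b.mean()
        var_a, var_b = a.var(), b.var()
        cov = float(np.mean((a - mu_a) * (b - mu_b)))
        return float(
            ((2 * mu_a * mu_b + _C1) * (2 * cov + _C2))
            / ((mu_a**2 + mu_b**2 + _C1) * (var_a + var_b + _C2))
        )
    if window_mode == "local":
        return float(
            structural_similarity(
                a, b,
                data_range=_PEAK,
                gaussian_weights=True,
                sigma=1.5,
                use_sample_covariance=False,
                K1=0.01,
                K2=0.03,
            )
        )
    raise ConfigurationError(f"unknown SSIM window_mode {window_mode!r}")


def evaluate_pair(ref, test, image_id: str | None = None,
                  noise_level: float | None = None,
                  ssim_mode: str = "local") -> MetricsReport:
    return MetricsReport(
        psnr=psnr(ref, test),
        ssim=ssim(ref, test, window_mode=ssim_mode),
        image_id=image_id,
        noise_level=noise_level,
    )
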