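"""Synthetic brain-like phantoms and Rician corruption.

The phantom generator produces piecewise-smooth 2-D images that exercise
the structure classes a denoiser must preserve: flat regions (nested
elliptical "tissue" shells), a smooth intensity ramp, a thin curvilinear
band, and a zero-intensity background margin large enough for
background-based noise estimation.

Rician corruption follows the magnitude-of-complex-Gaussian model: given a
clean magnitude image A and per-channel Gaussian noise of standard
deviation sigma in the real and imaginary channels,

    A_noisy = sqrt((A + nR)^2 + nI^2),   nR, nI ~ N(0, sigma^2) i.i.d.

so that E[A_noisy^2] = A^2 + 2 sigma^2 (the additive bias of the squared
magnitude). Noise levels are conventionally quoted as a proportion mu of
the clean image maximum: sigma = mu * max(A).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .utils import as_image

#: Default tissue palette: zero background plus five gray levels in
#: ascending order toward the center, with a uniform ~40-unit contrast
#: between adjacent shells (loosely mimicking CSF/GM/WM ordering in a
#: T1-weighted slice).
DEFAULT_LEVELS = (0.0, 70.0, 110.0, 150.0, 190.0, 230.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic description of a synthetic phantom.

    ``intensity_levels[0]`` is the background; the remaining levels fill
    the nested elliptical shells from the outside in. The same spec and
    seed always produce the bitwise-identical image.
    """

    height: int = 64
    width: int = 64
    n_ellipses: int = 5
    intensity_levels: tuple[float, ...] = DEFAULT_LEVELS
    thin_structure_width: int = 2
    ramp_amplitude: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ConfigurationError("phantom dimensions must be >= 32")
        if self.n_ellipses < 0:
            raise ConfigurationError("n_ellipses must be >= 0")
        if len(self.intensity_levels) == 0:
            raise ConfigurationError("at least one intensity level (background) required")
        if self.n_ellipses > 0 and len(self.intensity_levels) < 2:
            raise ConfigurationError("ellipses need at least one tissue level")
        for v in self.intensity_levels:
            if not (0.0 <= v <= 255.0):
                raise ConfigurationError(f"intensity level {v} outside [0, 255]")
        if self.thin_structure_width < 0:
            raise ConfigurationError("thin_structure_width must be >= 0")
        if self.ramp_amplitude < 0:
            raise ConfigurationError("ramp_amplitude must be >= 0")


@dataclass(frozen=True)
class RicianParams:
    """Per-channel Gaussian std of the complex noise, plus RNG seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom described by ``spec``.

    Pure function of (spec, seed): identical inputs give bitwise-identical
    images. With ``n_ellipses == 0`` the image is constant at the
    background level. The elliptical stack covers at most ~2/3 of the
    frame so that >= 10% of the pixels remain exact background.
    """
    h, w = spec.height, spec.width
    levels = spec.intensity_levels
    img = np.full((h, w), float(levels[0]))
    if spec.n_ellipses == 0:
        return img

    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = h / 2.0 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2.0 + rng.uniform(-0.02, 0.02) * w
    tissue = levels[1:]
    n = spec.n_ellipses
    outer_ry, outer_rx = 0.45 * h, 0.47 * w

    masks = []
    for k in range(n):
        frac = 1.0 if n == 1 else 0.25 + 0.75 * (n - 1 - k) / (n - 1)
        ry = outer_ry * frac * rng.uniform(0.95, 1.0)
        rx = outer_rx * frac * rng.uniform(0.95, 1.0)
        theta = 0.0 if k == 0 else rng.uniform(-0.3, 0.3)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        img[mask] = float(tissue[k % len(tissue)])
        masks.append(mask)

    # Smooth horizontal ramp confined to the innermost shell, so the outer
    # shells keep at least one strictly constant region.
    if spec.ramp_amplitude > 0:
        inner = masks[-1]
        if inner.any():
            cols = xx[inner]
            span = max(cols.max() - cols.min(), 1.0)
            img[inner] += spec.ramp_amplitude * (cols - cols.min()) / span

    # Thin sinusoidal band at the brightest level, clipped to the tissue.
    if spec.thin_structure_width > 0:
        tw = spec.thin_structure_width
        phase = rng.uniform(0.0, 2.0 * np.pi)
        cols = np.arange(w)
        center_rows = np.rint(
            cy + 0.22 * h * np.sin(4.0 * np.pi * cols / w + phase)
        ).astype(int)
        band = np.zeros((h, w), dtype=bool)
        for off in range(tw):
            rows = center_rows - tw // 2 + off
            ok = (rows >= 0) & (rows < h)
            band[rows[ok], cols[ok]] = True
        band &= masks[0]
        img[band] = float(max(tissue))

    np.clip(img, 0.0, 255.0, out=img)
    return img


def add_rician_noise(img, p: RicianParams) -> np.ndarray:
    """Corrupt a non-negative magnitude image with Rician noise.

    The real-channel stream nR is drawn before the imaginary-channel
    stream nI from a single seeded generator, so results are reproducible
    bit for bit. sigma = 0 returns the input unchanged (up to dtype).
    """
    a = as_image(img)
    if (a < 0).any():
        raise InputError("clean magnitude image must be non-negative")
    rng = np.random.default_rng(p.seed)
    n_r = rng.normal(0.0, p.sigma, size=a.shape) if p.sigma > 0 else 0.0
    n_i = rng.normal(0.0, p.sigma, size=a.shape) if p.sigma > 0 else 0.0
    return np.hypot(a + n_r, n_i)


def noise_level_to_sigma(mu: float, clean) -> float:
    """Convert a noise proportion to sigma: ``sigma = mu * max(clean)``."""
    if not (0.0 <= mu <= 1.0):
        raise ConfigurationError("noise proportion mu must lie in [0, 1]")
    a = as_image(clean, "clean")
    return float(mu) * float(a.max())


def quantize_uint8(img) -> np.ndarray:
    """Optional export step: round and clip to 8-bit."""
    a = as_image(img)
    return np.clip(np.rint(a), 0, 255).astype(np.uint8)
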