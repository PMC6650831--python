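"""Nonlocal means: feature-guided (the core filter) and classic patch-based.

Each output pixel is a convex combination of the pixels in its search
window, with weights

    w(x, y) = exp(-Dis(x, y) / h^2) / Z(x)

normalized to sum to one over the window. The dissimilarity Dis is either
the per-feature mean squared difference of the two LEPNet feature vectors
(feature-guided variant) or a Gaussian-weighted squared difference of the
two similarity-window patches (classic variant). The decay parameter
follows the rule of thumb h = C * sigma with sigma the Rician noise level.

Search windows are clipped at the image border (no synthetic pixels enter
the average); classic patch distances use reflect padding. The center
pixel participates with distance zero and no special capping.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError
from .lepnet import FeatureField
from .utils import as_image


@dataclass(frozen=True)
class NlmConfig:
    """Windows, decay constant and (derived) decay parameter.

    ``h`` is usually derived via :func:`decay_parameter` and stored with
    :func:`dataclasses.replace`; filtering requires h > 0.
    """

    search_window: int = 17
    similarity_window: int = 7
    C: float = 1.0
    alpha: float = 1.0
    h: float | None = None

    def __post_init__(self) -> None:
        for name, w in (("search_window", self.search_window),
                        ("similarity_window", self.similarity_window)):
            if w < 3 or w % 2 == 0:
                raise ConfigurationError(f"{name} must be odd and >= 3, got {w}")
        if self.C <= 0:
            raise ConfigurationError("decay constant C must be > 0")
        if self.alpha <= 0:
            raise ConfigurationError("patch-kernel std alpha must be > 0")
        if self.h is not None and self.h <= 0:
            raise ConfigurationError("decay parameter h must be > 0")

    def with_h(self, h: float) -> "NlmConfig":
        return replace(self, h=h)


def decay_parameter(sigma: float, C: float = 1.0) -> float:
    """Rule-of-thumb decay bandwidth: h = C * sigma."""
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")
    if C <= 0:
        raise ConfigurationError("C must be > 0")
    return C * sigma


def _require_h(cfg: NlmConfig) -> float:
    if cfg.h is None or cfg.h <= 0:
        raise ConfigurationError(
            "decay parameter h is unset; derive it with decay_parameter(sigma, C)"
        )
    return float(cfg.h)


def feature_distance(F: FeatureField, p1, p2) -> float:
    """Squared Euclidean distance between two feature vectors, divided by
    the vector length (so h = C*sigma keeps a comparable meaning whatever
    the filter count)."""
    v1 = F.at(*p1)
    v2 = F.at(*p2)
    return float(np.mean((v1 - v2) ** 2))


@dataclass
class WeightMap:
    """Normalized similarity weights of one search window.

    ``weights[r - origin[0], c - origin[1]]`` is the weight of pixel
    (r, c); ``origin`` is the top-left corner of the clipped window and
    ``normalizer`` the pre-normalization sum.
    """

    center: tuple[int, int]
    origin: tuple[int, int]
    weights: np.ndarray
    normalizer: float


def similarity_weights(F: FeatureField, center, cfg: NlmConfig) -> WeightMap:
    """Weights of Eq-style NLM for one pixel over its clipped search window."""
    h = _require_h(cfg)
    i, j = center
    H, W = F.image_shape
    if not (0 <= i < H and 0 <= j < W):
        raise InputError(f"center {center} outside image {F.image_shape}")
    sr = cfg.search_window // 2
    r0, r1 = max(0, i - sr), min(H, i + sr + 1)
    c0, c1 = max(0, j - sr), min(W, j + sr + 1)
    block = F.maps[:, r0:r1, c0:c1]
    v = F.maps[:, i, j][:, None, None]
    d = ((block - v) ** 2).mean(axis=0)
    raw = np.exp(-d / h**2)
    Z = float(raw.sum())
    return WeightMap(center=(i, j), origin=(r0, c0), weights=raw / Z, normalizer=Z)


def _feature_nlm_apply(values: np.ndarray, maps: np.ndarray, h: float,
                       search_window: int) -> np.ndarray:
    """Weighted average of ``values`` with feature-derived weights.

    Vectorized over window offsets; for every offset the per-pixel
    feature distance map drives the unnormalized weight, and numerator
    and normalizer are accumulated only where the offset target is in
    bounds (border clipping).
    """
    _, m, n = maps.shape
    sr = search_window // 2
    num = np.zeros((m, n))
    Z = np.zeros((m, n))
    h2 = h * h
    for dr in range(-sr, sr + 1):
        for dc in range(-sr, sr + 1):
            r0, r1 = max(0, -dr), m - max(0, dr)
            c0, c1 = max(0, -dc), n - max(0, dc)
            if r0 >= r1 or c0 >= c1:
                continue
            a = maps[:, r0:r1, c0:c1]
            b = maps[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            d = ((a - b) ** 2).mean(axis=0)
            w = np.exp(-d / h2)
            num[r0:r1, c0:c1] += w * values[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            Z[r0:r1, c0:c1] += w
    return num / Z


def nlm_denoise_features(noisy, F: FeatureField, cfg: NlmConfig) -> np.ndarray:
    """Feature-guided NLM: average the noisy image under weights computed
    from the LEPNet feature field."""
    a = as_image(noisy, "noisy")
    if a.shape != F.image_shape:
        raise InputError(
            f"feature field {F.image_shape} incongruent with image {a.shape}"
        )
    h = _require_h(cfg)
    return _feature_nlm_apply(a, F.maps, h, cfg.search_window)


def _gaussian_patch_kernel(size: int, alpha: float) -> np.ndarray:
    r = size // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    g = np.exp(-(yy**2 + xx**2) / (2.0 * alpha**2))
    return g / g.sum()


def tnlm_denoise(noisy, cfg: NlmConfig) -> np.ndarray:
    """Classic patch-based NLM.

    Patch dissimilarity is the Gaussian(alpha)-weighted mean squared
    difference of the two reflect-padded similarity-window patches.
    """
    a = as_image(noisy, "noisy")
    h = _require_h(cfg)
    pr = cfg.similarity_window // 2
    sr = cfg.search_window // 2
    G = _gaussian_patch_kernel(cfg.similarity_window, cfg.alpha)
    P = np.pad(a, pr, mode="reflect")
    m, n = a.shape
    num = np.zeros((m, n))
    Z = np.zeros((m, n))
    h2 = h * h
    for dr in range(-sr, sr + 1):
        for dc in range(-sr, sr + 1):
            r0, r1 = max(0, -dr), m - max(0, dr)
            c0, c1 = max(0, -dc), n - max(0, dc)
            if r0 >= r1 or c0 >= c1:
                continue
            xb = P[r0 : r1 + 2 * pr, c0 : c1 + 2 * pr]
            yb = P[r0 + dr : r1 + dr + 2 * pr, c0 + dc : c1 + dc + 2 * pr]
            dsq = (xb - yb) ** 2
            # full correlation then center crop == 'valid' patch sums
            dis = ndimage.correlate(dsq, G, mode="constant")
            if pr:
                dis = dis[pr:-pr, pr:-pr]
            w = np.exp(-dis / h2)
            num[r0:r1, c0:c1] += w * a[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            Z[r0:r1, c0:c1] += w
    return num / Z
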