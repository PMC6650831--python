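"""LEPNet: a two-layer convolutional network whose filters are learned
with Laplacian eigenmaps over image patches.

The network follows the PCANet template — cascaded unsupervised
convolutional filter banks followed by a simple nonlinearity — but the
filters minimize the locality-preserving objective on a K-nearest-
neighbour heat-kernel graph of mean-removed patches instead of maximizing
variance. Because convolution kernels must live in patch space (k1*k2
dimensions) rather than over the patch samples, the eigenmap objective is
solved in its linearized, locality-preserving-projection form: with Q the
matrix of mean-removed patch columns, W the graph affinity, D its degree
matrix and L = D - W the graph Laplacian, filters are generalized
eigenvectors of

    (Q L Q^T) v = lambda (Q D Q^T) v,

taken in ascending eigenvalue order. The pencil is solved on the
numerical range of Q (via an SVD basis), which both removes the constant
patch direction — mean removal makes it a common null vector of both
sides — and keeps the right-hand side positive definite; a ridge fallback
covers residual ill-conditioning. Kernels are normalized to unit
Frobenius norm with their largest-magnitude entry made positive so that
training is reproducible despite eigenvector sign/scale ambiguity.

Feature extraction convolves the input with the first bank, each of the
L1 maps with the second bank, and passes the L1*L2 maps through a
LeakyReLU whose negative branch divides by the slope constant ``a``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, ndimage, sparse
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, InputError
from .utils import as_image

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# patch harvesting

@dataclass
class PatchMatrix:
    """Mean-removed, vectorized patches stacked column-wise.

    ``data`` has shape (k1*k2, n_patches); column j is the row-major
    raveling of the patch recorded in ``sources[j] = (image, row, col)``
    with its mean subtracted.
    """

    data: np.ndarray
    patch_shape: tuple[int, int]
    sources: np.ndarray

    @property
    def n_patches(self) -> int:
        return self.data.shape[1]


def harvest_patches(images, patch_shape=(7, 7), max_patches=4000, seed=0) -> PatchMatrix:
    """Sample patches uniformly without replacement across all images.

    All valid top-left positions of all images form one pool; up to
    ``max_patches`` are drawn with a seeded generator, mean-removed and
    vectorized row-major.
    """
    k1, k2 = patch_shape
    if max_patches < 1:
        raise ConfigurationError("max_patches must be >= 1")
    imgs = [as_image(im, f"images[{i}]") for i, im in enumerate(images)]
    if not imgs:
        raise InputError("at least one image required")
    counts = []
    for i, im in enumerate(imgs):
        if im.shape[0] < k1 or im.shape[1] < k2:
            raise InputError(f"images[{i}] of shape {im.shape} smaller than patch {patch_shape}")
        counts.append((im.shape[0] - k1 + 1) * (im.shape[1] - k2 + 1))
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1])
    rng = np.random.default_rng(seed)
    take = min(max_patches, total)
    sel = rng.choice(total, size=take, replace=False)

    data = np.empty((k1 * k2, take))
    sources = np.empty((take, 3), dtype=np.int64)
    for j, flat in enumerate(sel):
        i = int(np.searchsorted(offsets, flat, side="right")) - 1
        local = int(flat - offsets[i])
        n_cols = imgs[i].shape[1] - k2 + 1
        r, c = divmod(local, n_cols)
        vec = imgs[i][r : r + k1, c : c + k2].ravel()
        data[:, j] = vec - vec.mean()
        sources[j] = (i, r, c)
    return PatchMatrix(data=data, patch_shape=(k1, k2), sources=sources)


# ---------------------------------------------------------------------------
# affinity graph

@dataclass
class AffinityGraph:
    """K-NN heat-kernel graph over patch samples: W, degree D, Laplacian L."""

    W: sparse.csr_matrix
    D: sparse.csr_matrix
    L: sparse.csr_matrix
    K: int
    t: float


def build_affinity(P: PatchMatrix, K: int = 10, t: float | None = None) -> AffinityGraph:
    """Build the symmetrized K-NN graph with heat-kernel weights
    ``exp(-||x_p - x_q||^2 / t)``.

    Edges are OR-symmetrized (p~q if either is among the other's K nearest
    neighbours). When ``t`` is omitted it is self-tuned to the mean
    squared K-NN distance of the sample. Duplicate patches get weight 1.
    """
    n = P.n_patches
    if not (1 <= K < n):
        raise InputError(f"need 1 <= K < n_patches, got K={K}, n={n}")
    X = np.ascontiguousarray(P.data.T)
    nn = NearestNeighbors(n_neighbors=K + 1).fit(X)
    dist, ind = nn.kneighbors(X)

    rows, cols, d2 = [], [], []
    for i in range(n):
        kept = 0
        for j, dd in zip(ind[i], dist[i]):
            if j == i:
                continue
            rows.append(i)
            cols.append(int(j))
            d2.append(dd * dd)
            kept += 1
            if kept == K:
                break
    d2 = np.asarray(d2)
    if t is None:
        t = float(d2.mean())
        if t <= 0:
            t = 1.0
    elif t <= 0:
        raise ConfigurationError("heat-kernel parameter t must be > 0")

    A = sparse.coo_matrix((np.exp(-d2 / t), (rows, cols)), shape=(n, n)).tocsr()
    W = A.maximum(A.T)
    deg = np.asarray(W.sum(axis=1)).ravel()
    D = sparse.diags(deg).tocsr()
    L = (D - W).tocsr()
    return AffinityGraph(W=W, D=D, L=L, K=K, t=t)


# ---------------------------------------------------------------------------
# filter learning

@dataclass
class FilterBank:
    """Ordered unit-norm convolution kernels with their eigenvalues."""

    kernels: np.ndarray  # (n_filters, k1, k2)
    eigenvalues: np.ndarray  # ascending
    layer_index: int = 1

    @property
    def n_filters(self) -> int:
        return self.kernels.shape[0]


def lpp_matrices(P: PatchMatrix, G: AffinityGraph, rank_rtol: float = 1e-10):
    """Assemble the reduced locality-preserving pencil (A, B) on the
    numerical range of the patch matrix.

    Returns ``(A, B, U)`` where U's columns are an orthonormal basis of
    the patch-sample range, ``A = U^T Q L Q^T U`` and
    ``B = U^T Q D Q^T U``. A ridge is added to B if it is still nearly
    singular (logged).
    """
    Q = P.data
    U, s, _ = np.linalg.svd(Q, full_matrices=False)
    if s[0] <= 0:
        raise InputError("patch matrix is identically zero")
    rank = int(np.sum(s > rank_rtol * s[0]))
    U = U[:, :rank]
    Qr = U.T @ Q
    A = Qr @ (G.L @ Qr.T)
    B = Qr @ (G.D @ Qr.T)
    A = (A + A.T) / 2.0
    B = (B + B.T) / 2.0
    bw = linalg.eigvalsh(B)
    if bw[0] <= 1e-12 * max(bw[-1], 1.0):
        eps = 1e-8 * (np.trace(B) / B.shape[0] + 1.0)
        logger.info("degree pencil nearly singular; adding ridge %.3e", eps)
        B = B + eps * np.eye(B.shape[0])
    return A, B, U


def _near_constant(v: np.ndarray) -> bool:
    u = v / np.linalg.norm(v)
    return abs(u.sum()) / np.sqrt(u.size) > 0.99


def solve_lep_filters(P: PatchMatrix, G: AffinityGraph, n_filters: int,
                      layer_index: int = 1) -> FilterBank:
    """Solve the locality-preserving eigenproblem and reshape the leading
    eigenvectors into convolution kernels.

    Eigenvalues are sorted ascending; any near-null eigenpair whose vector
    is essentially constant (the trivial embedding direction) is dropped;
    the first ``n_filters`` remaining vectors are reshaped row-major to
    k1 x k2, scaled to unit Frobenius norm, and sign-fixed so the
    largest-magnitude entry is positive.
    """
    k1, k2 = P.patch_shape
    if n_filters < 1 or n_filters > k1 * k2:
        raise InputError(f"n_filters must lie in [1, {k1 * k2}]")
    A, B, U = lpp_matrices(P, G)
    vals, vecs = linalg.eigh(A, B)
    scale = max(np.abs(vals).max(), np.finfo(float).tiny)

    kernels, eigenvalues = [], []
    for i in range(len(vals)):
        full = U @ vecs[:, i]
        if vals[i] < 1e-8 * scale and _near_constant(full):
            continue
        ker = full.reshape(k1, k2)
        ker = ker / np.linalg.norm(ker)
        if ker.flat[np.argmax(np.abs(ker))] < 0:
            ker = -ker
        kernels.append(ker)
        eigenvalues.append(vals[i])
        if len(kernels) == n_filters:
            break
    if len(kernels) < n_filters:
        raise InputError(
            f"patch sample supports only {len(kernels)} filters, {n_filters} requested"
        )
    return FilterBank(
        kernels=np.stack(kernels),
        eigenvalues=np.asarray(eigenvalues),
        layer_index=layer_index,
    )


# ---------------------------------------------------------------------------
# convolution and activation

def convolve_bank(img, bank: FilterBank) -> np.ndarray:
    """2-D correlation with each kernel, reflect-padded, 'same' output.
    Returns an array of shape (n_filters, H, W)."""
    a = as_image(img)
    k1, k2 = bank.kernels.shape[1:]
    if a.shape[0] < k1 or a.shape[1] < k2:
        raise InputError(f"image {a.shape} smaller than kernel ({k1}, {k2})")
    return np.stack(
        [ndimage.correlate(a, k, mode="reflect") for k in bank.kernels]
    )


def leaky_relu(x, a: float = 3.0):
    """Pass non-negative values; divide negatives by the slope constant."""
    if a <= 0:
        raise ConfigurationError("LeakyReLU slope divisor a must be > 0")
    arr = np.asarray(x, dtype=np.float64)
    out = np.where(arr >= 0, arr, arr / a)
    return float(out) if arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# model

@dataclass(frozen=True)
class LepNetConfig:
    """Training hyperparameters.

    ``n_filters`` gives the bank size per layer (two entries for the
    standard two-layer network; more entries stack deeper). ``heat_t``
    of ``None`` self-tunes the heat kernel per layer.
    """

    patch_shape: tuple[int, int] = (7, 7)
    n_filters: tuple[int, ...] = (12, 12)
    k_neighbors: int = 10
    heat_t: float | None = None
    max_patches: int = 4000
    leaky_a: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_filters) < 1 or any(n < 1 for n in self.n_filters):
            raise ConfigurationError("n_filters must be positive per layer")
        if self.leaky_a <= 0:
            raise ConfigurationError("leaky_a must be > 0")


@dataclass
class LepNetModel:
    """Trained filter banks plus the activation slope and provenance."""

    banks: list[FilterBank]
    leaky_a: float
    patch_shape: tuple[int, int]
    manifest: dict = field(default_factory=dict)

    @property
    def bank1(self) -> FilterBank:
        return self.banks[0]

    @property
    def bank2(self) -> FilterBank:
        return self.banks[1]

    @property
    def n_features(self) -> int:
        out = 1
        for b in self.banks:
            out *= b.n_filters
        return out

    def save(self, path) -> None:
        """Serialize to an .npz array container with a JSON sidecar manifest."""
        path = Path(path)
        arrays = {"leaky_a": np.float64(self.leaky_a),
                  "patch_shape": np.asarray(self.patch_shape),
                  "n_layers": np.int64(len(self.banks))}
        for i, b in enumerate(self.banks):
            arrays[f"kernels_{i}"] = b.kernels
            arrays[f"eigenvalues_{i}"] = b.eigenvalues
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def load(cls, path) -> "LepNetModel":
        path = Path(path)
        with np.load(path) as z:
            n_layers = int(z["n_layers"])
            banks = [
                FilterBank(kernels=z[f"kernels_{i}"],
                           eigenvalues=z[f"eigenvalues_{i}"],
                           layer_index=i + 1)
                for i in range(n_layers)
            ]
            leaky_a = float(z["leaky_a"])
            patch_shape = tuple(int(v) for v in z["patch_shape"])
        sidecar = path.with_suffix(".json")
        manifest = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(banks=banks, leaky_a=leaky_a, patch_shape=patch_shape,
                   manifest=manifest)


@dataclass
class FeatureField:
    """Per-pixel feature vectors as a stack of maps, shape (L, H, W)."""

    maps: np.ndarray

    @property
    def vector_length(self) -> int:
        return self.maps.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    def at(self, row: int, col: int) -> np.ndarray:
        return self.maps[:, row, col]


def lepnet_train(training_images, config: LepNetConfig = LepNetConfig()) -> LepNetModel:
    """Learn the cascaded filter banks.

    The first bank is learned from patches of the (pre-denoised) training
    images; every image is then convolved with it and the second bank is
    learned from patches harvested from all first-layer maps pooled
    together, and so on for deeper configurations.
    """
    maps = [as_image(im, f"training_images[{i}]") for i, im in enumerate(training_images)]
    if not maps:
        raise InputError("at least one training image required")
    n_images = len(maps)
    banks: list[FilterBank] = []
    patches_per_layer = []
    for li, nf in enumerate(config.n_filters):
        P = harvest_patches(maps, config.patch_shape, config.max_patches,
                            seed=config.seed + li)
        G = build_affinity(P, config.k_neighbors, config.heat_t)
        bank = solve_lep_filters(P, G, nf, layer_index=li + 1)
        logger.info("layer %d: %d patches, %d filters, t=%.4g",
                    li + 1, P.n_patches, nf, G.t)
        banks.append(bank)
        patches_per_layer.append(P.n_patches)
        if li < len(config.n_filters) - 1:
            maps = [m2 for m in maps for m2 in convolve_bank(m, bank)]
    manifest = {
        "n_training_images": n_images,
        "patches_per_layer": patches_per_layer,
        "n_filters": list(config.n_filters),
        "patch_shape": list(config.patch_shape),
        "k_neighbors": config.k_neighbors,
        "max_patches": config.max_patches,
        "seed": config.seed,
    }
    return LepNetModel(banks=banks, leaky_a=config.leaky_a,
                       patch_shape=config.patch_shape, manifest=manifest)


def lepnet_features(img, model: LepNetModel, activation: bool = True) -> FeatureField:
    """Extract the L1*L2 feature maps of an image.

    Maps are ordered first-layer-index major, second-layer-index minor.
    ``activation=False`` skips the LeakyReLU (the cascade is then linear),
    which is useful for diagnostics.
    """
    a = as_image(img)
    k1, k2 = model.patch_shape
    if a.shape[0] < k1 or a.shape[1] < k2:
        raise InputError(f"image {a.shape} smaller than patch ({k1}, {k2})")
    maps = [a]
    for bank in model.banks:
        maps = [m2 for m in maps for m2 in convolve_bank(m, bank)]
    F = np.stack(maps)
    if activation:
        F = leaky_relu(F, model.leaky_a)
    return FeatureField(maps=F)
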