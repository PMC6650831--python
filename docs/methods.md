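# Methods

## Noise model and estimation

The observed magnitude image is `Ã = sqrt((A + n_R)² + n_I²)` with
`n_R, n_I ~ N(0, σ²)` i.i.d. per pixel — Rician noise, reducing to a
Rayleigh distribution where the clean signal A is zero. Squaring makes
the noise bias additive and signal-independent, `E[Ã²] = A² + 2σ²`,
which the package uses twice: to estimate σ from the background and to
remove the bias after filtering.

`estimate_sigma` segments the background as the pixels strictly below
the Otsu threshold (256 histogram bins over the observed range, computed
on the raw image) and solves the background identity
`σ̂ = sqrt(mean(Ã²)/2)`. The estimator assumes the background is
*histogram-separable* from tissue. Two failure modes are worth knowing:

* On a pure-noise field the Otsu threshold splits the Rayleigh
  distribution itself and the truncated lower part underestimates σ by
  tens of percent. When the background support is known a priori, pass
  it via the `background` mask argument instead.
* On strongly multimodal images the binary Otsu split can assign the
  darkest tissue class to the background, inflating σ̂ (on the default
  synthetic phantom: ≈ +30% at 15% noise, up to ≈ 2.8× at 5% noise where
  the modes are narrow). This is a limitation of the single-threshold
  scheme; simulation studies that know σ should pass it explicitly to
  `lep_nlm_denoise(..., sigma=...)`.

## Filter learning

Training collects up to `max_patches` (default 4000) mean-removed 7×7
patches per layer, sampled uniformly without replacement across all
training images with a seeded generator. A K-nearest-neighbour graph
(default K = 10, OR-symmetrized) with heat-kernel weights
`exp(−d²/t)` is built over the sample; `t` is self-tuned to the mean
squared K-NN distance unless given. With Q the patch matrix, W the
affinity, D its degree matrix and L = D − W the graph Laplacian, the
filters solve the locality-preserving (linearized Laplacian-eigenmaps)
pencil

    (Q L Qᵀ) v = λ (Q D Qᵀ) v,

whose low-λ eigenvectors vary least between neighbouring patches on the
manifold. The pencil is solved on the SVD range of Q: mean removal makes
the constant patch direction a common null vector of both sides, so
restricting to the data range removes it exactly and keeps the
right-hand side positive definite (a logged ridge of 1e-8·mean-diagonal
covers residual ill-conditioning; a near-constant near-null eigenvector
is additionally dropped if one ever appears). Kernels are reshaped
row-major, normalized to unit Frobenius norm and sign-fixed (largest-
magnitude entry positive) — eigenvectors carry no inherent sign or
scale, and the convention makes training bit-reproducible.

A consequence worth stating: every learned kernel has exactly zero mean,
so the feature maps respond to structure, not to absolute intensity.
Flat regions of different brightness produce near-identical (near-zero)
features; intensity discrimination in the overall filter comes from the
search window being local and from the bias-corrected averaging, not
from the features.

The second bank is learned from patches pooled across *all* first-layer
maps of all training images (one shared bank, mirroring the PCANet
convention), with the layer's harvest seeded as `seed + layer_index`.
Deeper cascades are supported by giving `n_filters` more entries, but
two layers are the default; the returned features are the L1·L2 maps
after LeakyReLU (`x` if `x ≥ 0` else `x/a`, default a = 3, which
preserves the structural information carried by negative responses).

Defaults follow the reference configuration: 7×7 patches and kernels,
12 filters per layer (L = 144 features), a = 3. The tests and the
bundled small-model examples use 4 filters per layer (L = 16) on 64×64
phantoms; the method's behaviour does not change qualitatively and the
whole suite stays fast.

## Nonlocal means

For pixels x, y the dissimilarity is the squared Euclidean distance of
their feature vectors divided by the vector length L (so the decay rule
below is insensitive to the filter count); the classic baseline
(`tnlm_denoise`) instead uses the Gaussian(α)-weighted mean squared
difference of the two 7×7 patches (α default 1.0 — the reference leaves
it unspecified — with patches taken from the mirror-padded image).
Weights are `exp(−Dis/h²)`, normalized to sum to one over the 17×17
search window; windows are clipped at the image border, and the center
pixel participates with distance 0 and no special cap. The decay
parameter follows the rule of thumb `h = C·σ` with C default 1.0
(adjustable; larger C trades residual noise for smoothing), floored at
`h_min = 1e-3` so clean inputs degenerate to window averaging instead of
dividing by zero.

By default the averaging operates on squared intensities and subtracts
the additive `2σ̂²` bias (clipping at zero) before the final square
root. The alternative (`unbias=False`) averages magnitudes directly;
it is simpler but leaves the background its `σ·sqrt(π/2)` Rayleigh mean
offset, which no choice of weights can remove — on the 64×64 phantom at
15% noise this caps the attainable PSNR roughly 4 dB below the
bias-corrected mode. With bias correction enabled, the *entire*
filtering chain (main pass and method-noise recovery) runs in the
squared domain and the bias is subtracted exactly once at the end;
correcting only the main pass would let the recovery stage re-inject
the background bias.

## Method-noise detail recovery

The method noise (noisy − denoised, computed in whichever domain the
filter runs in) is filtered with the *same* feature-derived weights as
the main pass — the weights are a pure function of the feature field and
h, so reapplying them reproduces the cached weights exactly — then
smoothed with a 3×3 mirror-padded mean filter and added back. On pure
zero-mean noise both operations are contractive, so the step cannot
re-introduce more than a fraction of the removed noise; on structured
method noise it restores edges the main pass blurred. The returned
bundle satisfies `method_noise = noisy − denoised` and
`final = denoised + residual_details` bitwise.

## Synthetic phantoms

`make_phantom` renders piecewise-smooth anatomy: nested rotated ellipses
with five tissue gray levels ascending toward the center (defaults 70,
110, 150, 190, 230 — roughly CSF/GM/WM-like ordering with a uniform
~40-unit adjacent contrast), a smooth horizontal intensity ramp confined
to the innermost shell, a thin sinusoidal bright band, and an exact-zero
background covering about a third of the frame (the σ estimator needs
≥10%). Geometry is jittered by a seeded generator; the image is a pure
function of (spec, seed). Rician corruption draws the real-channel then
the imaginary-channel noise from one seeded generator, in floating
point; 8-bit quantization is a separate explicit step.

What the phantoms deliberately do *not* emulate: anatomical texture
(real tissue is nowhere flat), partial-volume voxels, bias fields,
multi-coil noise correlation, or 3-D continuity. Passing tests on these
phantoms therefore demonstrates the pipeline's mechanics — bias
handling, edge preservation, determinism — not clinical performance.
Where tests require the σ estimator's separability assumption to hold
(it is an assumption about the data, not a tunable), they use a
high-contrast phantom variant whose tissue levels all sit far above any
plausible threshold at the tested σ.

## Numerical choices

* Convolution is 2-D correlation with mirror padding ('same' output).
* The vectorized NLM engines iterate over window *offsets* and
  accumulate numerator and normalizer only where the offset target is in
  bounds; this is algebraically identical to the per-pixel double loop
  (tests pin the equivalence to 1e-10).
* The DCT prefilter uses orthonormal 8×8 blocks with stride 4 (final
  row/column positions appended so the image is fully covered), zeroes
  AC coefficients below 2.7σ, and averages overlapping reconstructions.
* Problem sizes in tests: 64×64 images, 4+4 filters, ≤2000 training
  patches, six training phantoms — small enough that the full suite and
  the end-to-end checks run in seconds while exercising every stage at
  the reference window/patch geometry.
* All stochastic stages (phantom geometry, noise, patch sampling) take
  explicit integer seeds; there is no hidden global RNG state, and two
  runs with equal seeds agree bitwise.

## Known limitations

* 2-D only; volumes are processed slice by slice along the last axis.
* The prefilter is a simplified DCT hard-thresholding stage (or classic
  NLM), not a rotationally-invariant prefiltered NLM; feature quality on
  real data will track prefilter quality.
* Zero-mean kernels mean the features carry no absolute-intensity
  channel (see above); on piecewise-constant images large flat regions
  of different levels are averaged together when they fall in the same
  search window, which bias-corrected averaging mitigates but does not
  remove.
* The Otsu-background σ estimator degrades on images whose darkest
  tissue class approaches the noise floor (high σ, dim tissue).
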