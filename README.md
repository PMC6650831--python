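# lepnlm

Rician-noise removal for 2-D magnetic-resonance images, built around a
nonlocal-means (NLM) filter whose patch-similarity weights are refined by
features from an unsupervised two-layer convolutional network. The
network's filter banks are learned with Laplacian eigenmaps (in their
linearized, locality-preserving-projection form) over mean-removed image
patches — a PCANet-style architecture with manifold-preserving filters
instead of principal components and a LeakyReLU output stage. A final
method-noise pass recovers details the main filter smoothed away.

The package is aimed at people studying or benchmarking MR denoisers: it
ships a synthetic brain-like phantom generator, the Rician corruption
model, a background-based noise estimator, the classic patch-based NLM
baseline, PSNR/SSIM metrics, and a CLI covering the whole workflow.

## The model

MR magnitude images carry Rician noise: with per-channel Gaussian noise
of std σ in the complex raw signal, the observed magnitude is
`Ã = sqrt((A + n_R)² + n_I²)`, so `E[Ã²] = A² + 2σ²`. The pipeline:

1. **σ estimation** — background pixels (below the Otsu threshold) are
   pure noise, so `σ̂ = sqrt(mean(Ã²_background) / 2)`.
2. **Prefilter** — a simple pluggable pre-denoiser (sliding 8×8 DCT hard
   thresholding at 2.7σ, classic NLM, or none) stabilizes feature
   extraction.
3. **Feature extraction** — two cascaded filter banks (default 12 + 12
   kernels of 7×7) learned by solving the generalized eigenproblem
   `(Q L Qᵀ) v = λ (Q D Qᵀ) v` over a K-NN heat-kernel patch graph
   (L = D − W its Laplacian); the input is convolved with bank 1, each
   map with bank 2, and the L1·L2 maps pass through LeakyReLU (a = 3),
   giving one feature vector per pixel.
4. **Feature-guided NLM** — each pixel is a convex combination of its
   17×17 search window with weights `exp(−‖ΔP‖²/L / h²)`, `h = C·σ̂`.
   By default averaging operates on squared intensities and the additive
   `2σ̂²` bias is subtracted at the end (the squared-magnitude domain is
   where Rician noise is additive and removable).
5. **Detail recovery** — the method noise (noisy − denoised) is filtered
   with the same weights, smoothed by a 3×3 mean filter, and added back.

## Worked example

```python
import lepnlm as lp

# train a small model on six clean synthetic phantoms
train = [lp.make_phantom(lp.PhantomSpec(64, 64, seed=100 + i)) for i in range(6)]
model = lp.lepnet_train(train, lp.LepNetConfig(n_filters=(4, 4), max_patches=2000, seed=0))

# simulate a 15%-noise acquisition
clean = lp.make_phantom(lp.PhantomSpec(64, 64, seed=999))
sigma = lp.noise_level_to_sigma(0.15, clean)          # 38.25
noisy = lp.add_rician_noise(clean, lp.RicianParams(sigma=sigma, seed=42))

bundle = lp.lep_nlm_denoise(noisy, model, lp.PipelineConfig())
for name, img in [("noisy", noisy), ("LEP-NLM_w", bundle.denoised),
                  ("LEP-NLM", bundle.final)]:
    print(f"{name:10s} PSNR {lp.psnr(clean, img):6.2f} dB  SSIM {lp.ssim(clean, img):.3f}")
```

prints

```
noisy      PSNR  15.27 dB  SSIM 0.358
LEP-NLM_w  PSNR  20.76 dB  SSIM 0.590
LEP-NLM    PSNR  21.32 dB  SSIM 0.599
```

i.e. the full filter gains ~6 dB PSNR and ~0.24 SSIM over the noisy
input on this phantom, and the method-noise recovery stage (`LEP-NLM`
vs the `LEP-NLM_w` variant without it) adds a further ~0.6 dB.

The same workflow is available from the shell:

```bash
lepnlm simulate --size 64 --noise-level 0.15 --seed 3 --out noisy.png --clean-out clean.png
lepnlm train --synthetic 6 --size 64 --l1 4 --l2 4 --out model.npz
lepnlm estimate-noise noisy.png
lepnlm denoise --input noisy.png --model model.npz --out denoised.png
lepnlm evaluate --clean clean.png --test noisy.png --test denoised.png
```

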