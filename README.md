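# dtswt

Wavelet-domain denoising of MRI and grayscale images, built around a
composite scheme: a real 2-D dual-tree discrete wavelet transform (DT-DWT)
splits the noisy image into six directional subbands, and each subband is
then denoised as if it were an image in its own right by soft thresholding in
the 2-D stationary wavelet transform (SWT) domain.  The package also ships
the baselines this scheme is compared against (SWT-only thresholding, soft
thresholding directly in the dual-tree domain, and the non-local means
filter), the full-reference quality metrics PSNR, SSIM, NMSE and FSIM, MRI-like
synthetic phantoms with Gaussian / salt-and-pepper / Poisson corruption
models, and a benchmark runner.  It is aimed at people evaluating classical
(transform-domain) denoisers on MR and grayscale images without depending on
external test images.

## Method

Let `I_b` be the noisy image, modeled as `I_b = I + n` with `n ~ N(0, σ²)`
i.i.d. per pixel.

1. **Analysis.** A one-level real 2-D dual-tree DWT (Farras nearly-symmetric
   10-tap first-stage pair; Kingsbury 10-tap q-shift pair at deeper levels)
   produces subbands `Wb{j}{s}`, with tree `j ∈ {1, 2}` and orientation
   `s ∈ {1, 2, 3}` (highpass along rows / columns / both), plus two lowpass
   planes.  Coefficients are scaled by `1/√2` per tree so the two trees form
   a tight frame.
2. **Per-subband SWT denoising.** Each `Wb{j}{s}` is treated as an image:
   it is decomposed by a 5-level db4 SWT (undecimated, periodic), every
   detail plane is soft-thresholded,
   `η_t(x) = sign(x)·max(|x| − t, 0)`, and the inverse SWT gives the
   denoised subband `Wd{j}{s}`.  The threshold is the universal
   (VisuShrink) rule `t = σ̂·√(2 ln n)` with `n` the plane's pixel count and
   `σ̂ = median(|d|)/0.6745` estimated from the level-1 diagonal detail.
   The two lowpass planes pass through unchanged.
3. **Synthesis.** The inverse dual-tree DWT (average of the two per-tree
   reconstructions) of `Wd{j}{s}` is the denoised image `I_d`.

The undecimated SWT is shift-covariant and the dual tree is nearly
shift-invariant with directional selectivity, which is what the composition
trades on: thresholding happens in a redundant, orientation-separated
representation instead of once in a critically sampled basis.

## Worked example

```bash
dtswt simulate clean.png --height 256 --width 256          # ellipse phantom
dtswt simulate noisy.png --height 256 --width 256 \
      --noise gaussian --sigma 20 --seed 0
dtswt metrics clean.png noisy.png
# PSNR: 22.7676   SSIM: 0.3111   NMSE: 0.0235   FSIM: 0.4016
dtswt denoise noisy.png denoised.png --method proposed
dtswt metrics clean.png denoised.png
# PSNR: 26.6697   SSIM: 0.6134   NMSE: 0.0096   FSIM: 0.5582
```

At σ = 20 the noisy phantom sits near `20·log10(255/20) ≈ 22.1 dB`; the
composite denoiser recovers roughly 4 dB of PSNR, halves the normalised
error energy and roughly doubles SSIM.  (The numbers above score the 8-bit
PNG round trip, so the noisy input reads slightly above 22.1 dB because
clipping to 0–255 removes some noise.)  The same experiment over methods,
noise levels and seeds:

```bash
dtswt benchmark --config bench.json --out results/
```

with a JSON config naming images (paths or `phantom:ellipses:256x256`),
methods (`proposed`, `swt`, `dt_soft`, `nlm`), a noise list and seeds; it
writes long-format `results.csv`, `results.json` and a mean-aggregated
`summary.csv` marking the best method per cell.

The same functionality is available as a library:

```python
from dtswt import DenoiseConfig, denoise_proposed, make_phantom, corrupt, NoiseSpec, compute_metrics

clean = make_phantom(256, 256, "ellipses")
noisy = corrupt(clean, NoiseSpec("gaussian", sigma=20.0, seed=0))
out = denoise_proposed(noisy, DenoiseConfig(clip_range=(0.0, 255.0)))
print(compute_metrics(clean, out, peak=255.0))
```

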