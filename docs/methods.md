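# Methods

## Model and procedure

The denoisers assume a single-channel image contaminated by additive white
Gaussian noise of standard deviation σ on a 0–255 intensity scale (impulse
and Poisson corruption models are provided for qualitative experiments, but
the threshold calibration is Gaussian).  Three wavelet-domain estimators and
one patch-based estimator are implemented:

1. **SWT thresholding** (`denoise_swt2d`): 5-level db4 stationary (à-trous,
   undecimated) decomposition with periodic boundaries; every detail plane
   at every level is soft-thresholded; the approximation plane is untouched;
   inverse SWT.
2. **Composite dual-tree + SWT scheme** (`denoise_proposed`): a one-level
   real dual-tree DWT produces six directional subbands `Wb{j}{s}` (tree j,
   orientation s) and two lowpass planes; each highpass subband is denoised
   by method 1 *as an image*; the lowpass planes pass through; inverse
   dual-tree transform.  The index pair is interpreted as (tree,
   orientation) at a single level — exactly six named highpass subbands —
   with multi-level decomposition supported but non-default.
3. **Dual-tree soft thresholding** (`denoise_dt_soft`): each dual-tree
   highpass subband is soft-thresholded directly, lowpass untouched.
4. **Non-local means** (`denoise_nlm`): patch-similarity weighted averaging,
   delegated to scikit-image's fast-mode implementation (patch 7, search
   window 21, `h = 0.8·σ̂` by default).

## Filters and transforms

* db4 scaling taps, the Farras nearly-symmetric 10-tap pair (first dual-tree
  stage) and the Kingsbury 10-tap q-shift pair (deeper stages) are package
  constants.  The commonly printed 8-decimal q-shift table is orthonormal
  only to ~8e-9, so the stored taps were projected once onto the
  double-shift orthonormality manifold (max change 2.4e-9 per tap, within
  the table's own rounding); all banks then achieve perfect reconstruction
  below 1e-10.
* Tree 2's first stage is the exact one-sample shift of tree 1's filters —
  the integer-delay construction that is sufficient at the first level —
  rather than the time-reversed pair some references use.
* Both transforms use periodic (circular) boundary handling, which makes
  round-trips exact and the SWT exactly shift-covariant; reflect padding
  happens once, upstream, via `pad_to_multiple` (multiple 32 for the SWT
  stage, 64 inside the composite scheme so every subband stays divisible by
  2^5).  The SWT engine is PyWavelets (`swt2`/`iswt2`, `norm=False`), so the
  level-1 detail of unit white noise keeps unit variance; the dual-tree
  transform is implemented in-package with per-tree 1/√2 scaling, making the
  two trees a tight frame (coefficient energy equals image energy).
* Orientation convention: "horizontal" always means highpass applied along
  the row axis, i.e. the plane that responds to horizontal edges; tests pin
  this with an explicit edge image.

## Threshold policy

The soft threshold value is not part of the method's definition, so it is an
explicit, configurable policy (`ThresholdRule`).  The default is the
universal (VisuShrink) rule `t = σ̂ √(2 ln n)` with

* `n` = pixel count of the plane being thresholded,
* `σ̂` = `median(|d|)/0.6745` from the level-1 diagonal detail of the SWT
  decomposition being thresholded (MAD is robust to sparse signal content
  and self-calibrates to the 1/√2 subband scale inside the composite
  scheme); `sigma_mode="known"` bypasses estimation,
* a multiplier (default 1.0) for exploration, and a `fixed` rule for exact
  control (threshold 0 turns every wavelet denoiser into a pure round trip,
  which the tests exploit).

Within one SWT decomposition all planes share n and σ̂, hence one threshold —
the simplest defensible completion.

## Synthetic data

`make_phantom` provides two deterministic 0–255 phantoms: a
piecewise-constant overlapping-ellipse "brain slice" (skull ring,
tissue, ventricles, lesions — at least four gray levels, sharp boundaries)
and a textured phantom (smooth background, a 30° sinusoidal grating, sharp
rectangles) whose dual-tree orientation energies are strongly anisotropic.
`corrupt` applies Gaussian (float, unclipped, so σ stays exactly
interpretable), salt-and-pepper, or scaled-Poisson noise through
`numpy.random.default_rng` (PCG64; streams are platform-stable for a given
seed).  At σ = 20 the corrupted phantom sits at `20 log10(255/20) ≈ 22.1 dB`
input PSNR, the calibration the evaluation protocol expects.

What the phantoms do *not* emulate: Rician/spatially correlated MRI noise,
bias fields, partial-volume effects, k-space artifacts, and the rich texture
of real anatomy.  Passing tests therefore demonstrate the transforms'
exactness and the pipeline's behaviour under the stated noise model, not
clinical performance.

## Metrics

PSNR, SSIM, NMSE and FSIM are implemented in-package.  SSIM uses the Wang et
al. defaults (11×11 Gaussian window, std 1.5, C1=(0.01·peak)²,
C2=(0.03·peak)², mean-pooled over fully valid window positions) and is
cross-checked against both a loop-based re-derivation and scikit-image.
FSIM uses the published constants (log-Gabor bank with 4 scales × 4
orientations, minimum wavelength 6, scale factor 2, σ_onf 0.55, angular
spread σ_θ = π/4/1.2, noise-compensation k = 2; Scharr 3×3 gradients;
T1 = 0.85, T2 = 160 on a 0–255 scale, intensities rescaled internally;
average-pool downsampling by `round(min_dim/256)`) and is cross-checked
against a loop-based re-derivation.  `peak` defaults to the dtype maximum
for integer images and the reference maximum for float images; benchmark
outputs are clipped to (0, peak) before scoring, the documented pipeline
endpoint.

## Known limitations

* With the default VisuShrink policy the SWT-only baseline can *lose* PSNR
  at σ = 10 on the ellipse phantom (MAD overestimates σ from sparse edge
  detail and the universal threshold is aggressive); the composite method
  still gains at every σ.
* On the piecewise-constant ellipse phantom the benchmark ranks direct
  dual-tree soft thresholding ~0.25 dB above the composite scheme at σ = 20,
  while on textured content (the texture phantom, natural test images) the
  composite scheme wins by small margins.  This is structural: a dual-tree
  highpass subband of a piecewise-constant image is a sparse field of edge
  responses, which a single soft threshold preserves near-optimally, whereas
  re-decomposing it with db4 spreads edge energy across SWT levels and loses
  some of it at each threshold.  The benchmark reports the ranking as
  computed; see `summary.csv`'s `best` column.
* Non-local means dominates all wavelet methods on the piecewise-constant
  phantom (patch redundancy is ideal there); the benchmark flags rather than
  hides this.
* Problem sizes used throughout the suite — 256² phantoms, 10 seeds per σ
  for efficacy means, 5 seeds for calibration checks — were chosen so the
  whole evaluation reruns in about a minute on one CPU while keeping
  seed-to-seed variation of the reported means below ~0.1 dB.
* Color images, 3-D volumes, Rician noise modeling and DICOM/NIfTI I/O are
  out of scope.
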