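"""The four denoising methods under comparison.

* :func:`denoise_swt2d` — soft thresholding of all detail planes of a 5-level
  db4 stationary wavelet decomposition.
* :func:`denoise_proposed` — the composite scheme: a dual-tree DWT splits the
  image into six directional subbands ``Wb{j}{s}`` (trees j=1,2, orientations
  s=1..3), each subband is treated as an image in its own right and denoised
  with the SWT scheme, and the dual-tree inverse reassembles the result from
  the denoised subbands ``Wd{j}{s}``.
* :func:`denoise_dt_soft` — soft thresholding applied directly to the
  dual-tree highpass subbands.
* :func:`denoise_nlm` — the non-local means filter (patch-similarity weighted
  averaging), as the non-wavelet baseline.

All methods accept/return 2-D float arrays, preserve shape, and convert to
float64 at entry.  Clipping to an intensity range is opt-in via
``DenoiseConfig.clip_range`` (callers working in 8-bit terms typically pass
``(0, 255)``); metrics should be computed on whatever the pipeline endpoint
is, so clipping happens last.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from skimage.restoration import denoise_nl_means

from .dualtree2d import dualtree2_forward, dualtree2_inverse
from .shrinkage import ThresholdRule, mad_sigma, resolve_threshold, soft_threshold
from .swt2d import pad_to_multiple, swt2_forward, swt2_inverse
from .wavelet_filters import get_dualtree_filters

__all__ = [
    "DenoiseConfig",
    "denoise_swt2d",
    "denoise_proposed",
    "denoise_dt_soft",
    "denoise_nlm",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters shared by the wavelet denoisers.

    swt_levels=5 and wavelet="db4" are the method's stated operating point;
    dt_levels=1 gives exactly the six named directional subbands.
    """

    wavelet: str = "db4"
    swt_levels: int = 5
    dt_levels: int = 1
    dt_filters: str = "farras+qshift10"
    threshold: ThresholdRule = field(default_factory=ThresholdRule)
    lowpass_policy: str = "passthrough"
    clip_range: tuple | None = None

    def __post_init__(self):
        if self.swt_levels < 1 or self.dt_levels < 1:
            raise ValueError("decomposition levels must be >= 1")
        if self.lowpass_policy not in ("passthrough", "denoise"):
            raise ValueError(f"unknown lowpass_policy {self.lowpass_policy!r}")


def _as_image(noisy: np.ndarray) -> np.ndarray:
    arr = np.asarray(noisy, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    return arr


def _clip(image: np.ndarray, config: DenoiseConfig) -> np.ndarray:
    if config.clip_range is None:
        return image
    lo, hi = config.clip_range
    return np.clip(image, lo, hi)


def _swt_threshold_core(image: np.ndarray, config: DenoiseConfig) -> np.ndarray:
    """Pad -> SWT -> soft-threshold every detail plane -> inverse -> crop."""
    padded, rec = pad_to_multiple(image, 2**config.swt_levels)
    coeffs = swt2_forward(padded, config.wavelet, config.swt_levels)
    reference = coeffs.details[0][2]  # level-1 diagonal, the sigma reference
    new_details = []
    for planes in coeffs.details:
        new_details.append(
            tuple(
                soft_threshold(
                    p, resolve_threshold(config.threshold, p, reference)
                )
                for p in planes
            )
        )
    coeffs.details = new_details
    return rec.crop(swt2_inverse(coeffs))


def denoise_swt2d(noisy: np.ndarray, config: DenoiseConfig | None = None) -> np.ndarray:
    """SWT-domain soft thresholding (the single-transform baseline)."""
    if config is None:
        config = DenoiseConfig()
    image = _as_image(noisy)
    return _clip(_swt_threshold_core(image, config), config)


def denoise_proposed(
    noisy: np.ndarray, config: DenoiseConfig | None = None
) -> np.ndarray:
    """Dual-tree decomposition with per-subband SWT denoising.

    The image is padded so every dual-tree subband is divisible by
    ``2**swt_levels``, each highpass subband ``Wb{j}{s}`` is denoised by the
    SWT scheme as if it were an image, and the dual-tree inverse reassembles
    the estimate from ``Wd{j}{s}``.
    """
    if config is None:
        config = DenoiseConfig()
    image = _as_image(noisy)
    multiple = 2 ** (config.dt_levels + config.swt_levels)
    padded, rec = pad_to_multiple(image, multiple)
    filters = get_dualtree_filters(config.dt_filters)
    coeffs = dualtree2_forward(padded, config.dt_levels, filters)
    # after padding every subband is still divisible by 2**swt_levels
    smallest = min(coeffs.lowpass[1].shape)
    if smallest % 2**config.swt_levels:
        raise ValueError(
            "dual-tree subbands are not divisible by 2^swt_levels; "
            "reduce swt_levels or pad the input further"
        )
    for key, band in coeffs.highpass.items():
        coeffs.highpass[key] = _swt_threshold_core(band, config)
    if config.lowpass_policy == "denoise":
        for tree in (1, 2):
            coeffs.lowpass[tree] = _swt_threshold_core(coeffs.lowpass[tree], config)
    return _clip(rec.crop(dualtree2_inverse(coeffs, filters)), config)


def denoise_dt_soft(
    noisy: np.ndarray, config: DenoiseConfig | None = None
) -> np.ndarray:
    """Soft thresholding applied directly in the dual-tree DWT domain."""
    if config is None:
        config = DenoiseConfig()
    image = _as_image(noisy)
    padded, rec = pad_to_multiple(image, 2**config.dt_levels)
    filters = get_dualtree_filters(config.dt_filters)
    coeffs = dualtree2_forward(padded, config.dt_levels, filters)
    for key, band in coeffs.highpass.items():
        t = resolve_threshold(config.threshold, band)
        coeffs.highpass[key] = soft_threshold(band, t)
    return _clip(rec.crop(dualtree2_inverse(coeffs, filters)), config)


def denoise_nlm(
    noisy: np.ndarray,
    patch_size: int = 7,
    search_window: int = 21,
    h: float | None = None,
) -> np.ndarray:
    """Non-local means: patch-similarity weighted averaging.

    ``search_window`` is the full width of the window of candidate patch
    centers.  When ``h`` is omitted it defaults to 0.8 * sigma-hat, with
    sigma-hat estimated by MAD from the level-1 diagonal wavelet detail.
    """
    image = _as_image(noisy)
    if patch_size % 2 == 0 or search_window % 2 == 0:
        raise ValueError("patch_size and search_window must be odd")
    if patch_size >= search_window:
        raise ValueError("patch_size must be smaller than search_window")
    if h is None:
        _, (_, _, diag) = pywt.dwt2(image, "db4", mode="periodization")
        h = 0.8 * mad_sigma(diag)
    return np.asarray(
        denoise_nl_means(
            image,
            patch_size=patch_size,
            patch_distance=(search_window - 1) // 2,
            h=float(h),
            fast_mode=True,
            sigma=0.0,
            preserve_range=True,
        ),
        dtype=np.float64,
    )
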