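"""Full-reference image quality metrics: PSNR, SSIM, NMSE and FSIM.

All four are implemented here rather than delegated, so the exact formulas
and constants are pinned in one place:

* PSNR = 10 log10(peak^2 / MSE), in dB (+inf for identical images).
* SSIM follows Wang et al.: an 11x11 Gaussian window (std 1.5), stability
  constants C1 = (0.01 peak)^2 and C2 = (0.03 peak)^2, the local map pooled
  by its mean over the fully-valid window positions.
* NMSE = ||ref - test||^2 / ||ref||^2 over all pixels.
* FSIM follows Zhang et al.: phase-congruency maps from a log-Gabor filter
  bank (4 scales, 4 orientations) and Scharr gradient magnitudes, combined
  as S_PC * S_G and pooled with weights max(PC1, PC2).  Intensities are
  rescaled to 0-255 internally so the published constants T1 = 0.85 and
  T2 = 160 keep their meaning.

``peak`` defaults to the dtype maximum for integer images and to the
reference maximum for float images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, signal

__all__ = ["MetricsReport", "psnr", "ssim", "nmse", "fsim", "compute_metrics", "infer_peak"]

# --- SSIM constants (Wang et al. defaults) ---------------------------------
_SSIM_WINDOW = 11
_SSIM_SIGMA = 1.5
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03

# --- FSIM constants (Zhang et al. / Kovesi phase congruency defaults) ------
_FSIM_T1 = 0.85  # phase-congruency similarity constant
_FSIM_T2 = 160.0  # gradient similarity constant (0-255 scale)
_PC_NSCALE = 4
_PC_NORIENT = 4
_PC_MIN_WAVELENGTH = 6.0
_PC_MULT = 2.0
_PC_SIGMA_ONF = 0.55
_PC_DTHETA_ON_SIGMA = 1.2
_PC_K = 2.0
_PC_EPSILON = 1e-4
_PC_CUTOFF = 0.45  # lowpass prefilter cutoff
_PC_SHARPNESS = 15  # lowpass prefilter order


def infer_peak(reference: np.ndarray) -> float:
    """Default peak: dtype max for integer images, data max for float."""
    reference = np.asarray(reference)
    if np.issubdtype(reference.dtype, np.integer):
        return float(np.iinfo(reference.dtype).max)
    return float(reference.max())


def _check_pair(reference, test):
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs test {test.shape}"
        )
    return reference, test


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical inputs."""
    reference, test = _check_pair(reference, test)
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def nmse(reference: np.ndarray, test: np.ndarray) -> float:
    """Error energy normalised by reference energy."""
    reference, test = _check_pair(reference, test)
    denom = float(np.sum(reference**2))
    if denom == 0.0:
        raise ValueError("reference image is identically zero")
    return float(np.sum((reference - test) ** 2) / denom)


def _gaussian_window(size: int = _SSIM_WINDOW, sigma: float = _SSIM_SIGMA):
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    k /= k.sum()
    return np.outer(k, k)


def ssim(reference: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Mean structural similarity over fully-valid 11x11 window positions."""
    reference, test = _check_pair(reference, test)
    if min(reference.shape) < _SSIM_WINDOW:
        raise ValueError(f"images must be at least {_SSIM_WINDOW} px per side")
    if peak <= 0:
        raise ValueError("peak must be positive")
    w = _gaussian_window()
    c1 = (_SSIM_K1 * peak) ** 2
    c2 = (_SSIM_K2 * peak) ** 2

    def f(img):
        return signal.fftconvolve(img, w, mode="valid")

    mu1, mu2 = f(reference), f(test)
    s11 = f(reference * reference) - mu1 * mu1
    s22 = f(test * test) - mu2 * mu2
    s12 = f(reference * test) - mu1 * mu2
    num = (2.0 * mu1 * mu2 + c1) * (2.0 * s12 + c2)
    den = (mu1**2 + mu2**2 + c1) * (s11 + s22 + c2)
    return float(np.mean(num / den))


# --------------------------------------------------------------------------
# FSIM


def _lowpass_filter(shape) -> np.ndarray:
    rows, cols = shape
    y = _freq_axis(rows)
    x = _freq_axis(cols)
    radius = np.sqrt(x[None, :] ** 2 + y[:, None] ** 2)
    return np.fft.ifftshift(1.0 / (1.0 + (radius / _PC_CUTOFF) ** (2 * _PC_SHARPNESS)))


def _freq_axis(n: int) -> np.ndarray:
    if n % 2:
        return (np.arange(n) - (n - 1) / 2.0) / (n - 1)
    return (np.arange(n) - n / 2.0) / n


def _phase_congruency(image: np.ndarray) -> np.ndarray:
    """Kovesi-style phase congruency map (4 scales x 4 orientations)."""
    rows, cols = image.shape
    y = _freq_axis(rows)
    x = _freq_axis(cols)
    xg, yg = np.meshgrid(x, y)
    radius = np.fft.ifftshift(np.sqrt(xg**2 + yg**2))
    theta = np.fft.ifftshift(np.arctan2(-yg, xg))
    radius[0, 0] = 1.0
    sintheta, costheta = np.sin(theta), np.cos(theta)
    lp = _lowpass_filter(image.shape)

    log_gabor = []
    for s in range(_PC_NSCALE):
        wavelength = _PC_MIN_WAVELENGTH * _PC_MULT**s
        g = np.exp(
            -(np.log(radius * wavelength) ** 2)
            / (2.0 * math.log(_PC_SIGMA_ONF) ** 2)
        )
        g *= lp
        g[0, 0] = 0.0
        log_gabor.append(g)

    theta_sigma = math.pi / _PC_NORIENT / _PC_DTHETA_ON_SIGMA
    im_fft = np.fft.fft2(image)
    energy_all = np.zeros(image.shape)
    an_all = np.zeros(image.shape)

    for o in range(_PC_NORIENT):
        angle = o * math.pi / _PC_NORIENT
        ds = sintheta * math.cos(angle) - costheta * math.sin(angle)
        dc = costheta * math.cos(angle) + sintheta * math.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))

        eo = []
        sum_e = np.zeros(image.shape)
        sum_o = np.zeros(image.shape)
        sum_an = np.zeros(image.shape)
        tau = 0.0
        for s in range(_PC_NSCALE):
            response = np.fft.ifft2(im_fft * log_gabor[s] * spread)
            an = np.abs(response)
            eo.append(response)
            sum_an += an
            sum_e += response.real
            sum_o += response.imag
            if s == 0:
                tau = float(np.median(an)) / math.sqrt(math.log(4.0))
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + _PC_EPSILON
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros(image.shape)
        for response in eo:
            energy += (
                response.real * mean_e
                + response.imag * mean_o
                - np.abs(response.real * mean_o - response.imag * mean_e)
            )
        # Rayleigh-model noise-energy threshold, per the published estimator
        total_tau = tau * (1.0 - (1.0 / _PC_MULT) ** _PC_NSCALE) / (
            1.0 - 1.0 / _PC_MULT
        )
        noise_mean = total_tau * math.sqrt(math.pi / 2.0)
        noise_sigma = total_tau * math.sqrt((4.0 - math.pi) / 2.0)
        t = (noise_mean + _PC_K * noise_sigma) / 1.7
        energy_all += np.maximum(energy - t, 0.0)
        an_all += sum_an
    return energy_all / (an_all + _PC_EPSILON)


_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0


def _gradient_magnitude(image: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(image, _SCHARR_X, mode="constant")
    gy = ndimage.convolve(image, _SCHARR_X.T, mode="constant")
    return np.sqrt(gx**2 + gy**2)


def fsim(reference: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Feature similarity (phase congruency + gradient, PC-weighted pooling)."""
    reference, test = _check_pair(reference, test)
    if min(reference.shape) < 32:
        raise ValueError("images must be at least 32 px per side for FSIM")
    if peak <= 0:
        raise ValueError("peak must be positive")
    ref = reference * (255.0 / peak)
    tst = test * (255.0 / peak)

    # published preprocessing: average-pool by F = round(min_dim / 256)
    factor = max(1, int(round(min(ref.shape) / 256.0)))
    if factor > 1:
        k = np.ones((factor, factor)) / factor**2
        ref = ndimage.convolve(ref, k, mode="constant")[::factor, ::factor]
        tst = ndimage.convolve(tst, k, mode="constant")[::factor, ::factor]

    pc1 = _phase_congruency(ref)
    pc2 = _phase_congruency(tst)
    g1 = _gradient_magnitude(ref)
    g2 = _gradient_magnitude(tst)

    s_pc = (2.0 * pc1 * pc2 + _FSIM_T1) / (pc1**2 + pc2**2 + _FSIM_T1)
    s_g = (2.0 * g1 * g2 + _FSIM_T2) / (g1**2 + g2**2 + _FSIM_T2)
    pcm = np.maximum(pc1, pc2)
    return float(np.sum(s_pc * s_g * pcm) / np.sum(pcm))


@dataclass(frozen=True)
class MetricsReport:
    """PSNR/SSIM/NMSE/FSIM for one (reference, test) pair."""

    psnr: float
    ssim: float
    nmse: float
    fsim: float
    peak: float

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["psnr"]):
            d["psnr"] = "inf"
        return d


def compute_metrics(
    reference: np.ndarray, test: np.ndarray, peak: float | None = None
) -> MetricsReport:
    """Evaluate all four metrics; ``peak`` defaults via :func:`infer_peak`."""
    if peak is None:
        peak = infer_peak(reference)
    return MetricsReport(
        psnr=psnr(reference, test, peak),
        ssim=ssim(reference, test, peak),
        nmse=nmse(reference, test),
        fsim=fsim(reference, test, peak),
        peak=float(peak),
    )
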