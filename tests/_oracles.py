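"""Independent, loop-based oracle evaluations used to cross-check the metrics.

These deliberately re-derive the published formulas from scratch (explicit
per-pixel loops, independently constructed windows and filters) and share no
code with ``dtswt.metrics``.
"""

from __future__ import annotations

import math

import numpy as np


def ssim_loop(reference: np.ndarray, test: np.ndarray, peak: float) -> float:
    """Windowed SSIM evaluated position by position over valid windows."""
    win = 11
    sigma = 1.5
    r = win // 2
    kernel = np.empty((win, win))
    for a in range(win):
        for b in range(win):
            kernel[a, b] = math.exp(-((a - r) ** 2 + (b - r) ** 2) / (2 * sigma**2))
    kernel /= kernel.sum()
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    h, w = reference.shape
    values = []
    for i in range(h - win + 1):
        for j in range(w - win + 1):
            x = reference[i : i + win, j : j + win]
            y = test[i : i + win, j : j + win]
            mu_x = float(np.sum(kernel * x))
            mu_y = float(np.sum(kernel * y))
            var_x = float(np.sum(kernel * x * x)) - mu_x**2
            var_y = float(np.sum(kernel * y * y)) - mu_y**2
            cov = float(np.sum(kernel * x * y)) - mu_x * mu_y
            values.append(
                ((2 * mu_x * mu_y + c1) * (2 * cov + c2))
                / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
            )
    return float(np.mean(values))


def _pc_loop(image: np.ndarray) -> np.ndarray:
    """Phase congruency, 4 log-Gabor scales x 4 orientations, loop-built filters."""
    nscale, norient = 4, 4
    min_wavelength, mult, sigma_onf = 6.0, 2.0, 0.55
    k_noise, eps = 2.0, 1e-4
    rows, cols = image.shape

    def freq(idx, n):
        # frequency sample at FFT index idx (DC at index 0)
        return ((idx + n // 2) % n) / n - 0.5 if n % 2 == 0 else (
            ((idx + (n - 1) // 2) % n) / (n - 1) - 0.5
        )

    radius = np.empty((rows, cols))
    theta = np.empty((rows, cols))
    for i in range(rows):
        fy = freq(i, rows)
        for j in range(cols):
            fx = freq(j, cols)
            radius[i, j] = math.hypot(fx, fy)
            theta[i, j] = math.atan2(-fy, fx)
    radius[0, 0] = 1.0

    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)
    gabors = []
    for s in range(nscale):
        lam = min_wavelength * mult**s
        g = np.exp(-(np.log(radius * lam) ** 2) / (2.0 * math.log(sigma_onf) ** 2))
        g = g * lowpass
        g[0, 0] = 0.0
        gabors.append(g)

    theta_sigma = math.pi / norient / 1.2
    fim = np.fft.fft2(image)
    energy_total = np.zeros((rows, cols))
    an_total = np.zeros((rows, cols))
    for o in range(norient):
        ang = o * math.pi / norient
        d_theta = np.abs(
            np.arctan2(
                np.sin(theta) * math.cos(ang) - np.cos(theta) * math.sin(ang),
                np.cos(theta) * math.cos(ang) + np.sin(theta) * math.sin(ang),
            )
        )
        spread = np.exp(-(d_theta**2) / (2.0 * theta_sigma**2))
        responses = [np.fft.ifft2(fim * g * spread) for g in gabors]
        sum_e = sum(r.real for r in responses)
        sum_o = sum(r.imag for r in responses)
        sum_an = sum(np.abs(r) for r in responses)
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + eps
        me, mo = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros((rows, cols))
        for r in responses:
            energy += r.real * me + r.imag * mo - np.abs(r.real * mo - r.imag * me)
        tau = float(np.median(np.abs(responses[0]))) / math.sqrt(math.log(4.0))
        total_tau = tau * (1 - (1 / mult) ** nscale) / (1 - 1 / mult)
        t = (total_tau * math.sqrt(math.pi / 2) + k_noise * total_tau * math.sqrt((4 - math.pi) / 2)) / 1.7
        energy_total += np.maximum(energy - t, 0.0)
        an_total += sum_an
    return energy_total / (an_total + eps)


def fsim_loop(reference: np.ndarray, test: np.ndarray, peak: float) -> float:
    """FSIM with loop-based gradients and per-pixel pooling."""
    t1, t2 = 0.85, 160.0
    ref = reference * (255.0 / peak)
    tst = test * (255.0 / peak)
    # no downsampling branch: oracle fixtures are < 512 px
    assert max(1, round(min(ref.shape) / 256.0)) == 1

    pc1, pc2 = _pc_loop(ref), _pc_loop(tst)

    def grad(img):
        h, w = img.shape
        padded = np.zeros((h + 2, w + 2))
        padded[1:-1, 1:-1] = img
        gx = np.empty((h, w))
        gy = np.empty((h, w))
        kx = [[3, 0, -3], [10, 0, -10], [3, 0, -3]]
        for i in range(h):
            for j in range(w):
                sx = sy = 0.0
                for a in range(3):
                    for b in range(3):
                        # convolution: kernel flipped against the neighbourhood
                        v = padded[i + 2 - a, j + 2 - b]
                        sx += kx[a][b] * v
                        sy += kx[b][a] * v
                gx[i, j] = sx / 16.0
                gy[i, j] = sy / 16.0
        return np.sqrt(gx**2 + gy**2)

    g1, g2 = grad(ref), grad(tst)
    num = den = 0.0
    h, w = ref.shape
    for i in range(h):
        for j in range(w):
            s_pc = (2 * pc1[i, j] * pc2[i, j] + t1) / (
                pc1[i, j] ** 2 + pc2[i, j] ** 2 + t1
            )
            s_g = (2 * g1[i, j] * g2[i, j] + t2) / (g1[i, j] ** 2 + g2[i, j] ** 2 + t2)
            pcm = max(pc1[i, j], pc2[i, j])
            num += s_pc * s_g * pcm
            den += pcm
    return num / den
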