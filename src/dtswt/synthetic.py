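"""MRI-like phantoms and noise models for fully self-contained experiments.

Two deterministic phantoms are provided: a piecewise-constant overlapping-
ellipse "brain slice" (sharp boundaries, several tissue-like gray levels) and
a textured phantom (smooth background, an oriented sinusoidal grating and
sharp edges) that exercises the directional subbands.  Corruption models are
additive Gaussian white noise with sigma on the 0-255 intensity scale,
salt-and-pepper impulse noise, and scaled Poisson shot noise.

All randomness goes through ``numpy.random.default_rng`` (PCG64), whose
streams are stable across platforms for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSpec", "make_phantom", "corrupt"]


@dataclass(frozen=True)
class NoiseSpec:
    """A corruption model: kind plus the parameters that kind needs.

    sigma
        Gaussian standard deviation, on the 0-255 scale.
    density
        Fraction of pixels hit by salt-and-pepper impulses.
    scale
        Poisson quantisation step: larger scale, stronger shot noise.
    """

    kind: str
    sigma: float = 0.0
    density: float = 0.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian", "salt_pepper", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


# (center_y, center_x, semi_y, semi_x, angle_deg, gray) in unit coordinates;
# later entries overwrite earlier ones (piecewise-constant painting).
_ELLIPSES = [
    (0.50, 0.50, 0.46, 0.36, 0.0, 235.0),  # skull
    (0.50, 0.50, 0.42, 0.32, 0.0, 150.0),  # brain tissue
    (0.42, 0.40, 0.13, 0.06, -18.0, 60.0),  # left ventricle
    (0.42, 0.60, 0.13, 0.06, 18.0, 60.0),  # right ventricle
    (0.68, 0.50, 0.10, 0.14, 0.0, 190.0),  # bright lesion
    (0.28, 0.52, 0.05, 0.05, 0.0, 110.0),  # small nucleus
    (0.58, 0.33, 0.045, 0.03, 30.0, 30.0),  # dark focus
]


def _paint_ellipses(height: int, width: int) -> np.ndarray:
    yy, xx = np.meshgrid(
        (np.arange(height) + 0.5) / height,
        (np.arange(width) + 0.5) / width,
        indexing="ij",
    )
    img = np.full((height, width), 20.0)
    for cy, cx, ay, ax, ang, gray in _ELLIPSES:
        t = np.deg2rad(ang)
        u = (yy - cy) * np.cos(t) - (xx - cx) * np.sin(t)
        v = (yy - cy) * np.sin(t) + (xx - cx) * np.cos(t)
        img[(u / ay) ** 2 + (v / ax) ** 2 <= 1.0] = gray
    return img


def _paint_texture(height: int, width: int) -> np.ndarray:
    yy, xx = np.meshgrid(
        np.arange(height) / height, np.arange(width) / width, indexing="ij"
    )
    img = 110.0 + 50.0 * np.cos(np.pi * xx) * np.cos(np.pi * yy)
    # oriented grating (30 degrees), period ~8 px at 256 wide
    theta = np.deg2rad(30.0)
    phase = 2.0 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) * (width / 8.0)
    band = (yy > 0.15) & (yy < 0.55) & (xx > 0.1) & (xx < 0.9)
    img[band] += 45.0 * np.sin(phase[band])
    # sharp bright rectangle and a dark stripe
    img[(yy > 0.65) & (yy < 0.85) & (xx > 0.2) & (xx < 0.45)] = 240.0
    img[(yy > 0.62) & (yy < 0.92) & (xx > 0.6) & (xx < 0.68)] = 15.0
    return np.clip(img, 0.0, 255.0)


def make_phantom(height: int, width: int, kind: str = "ellipses") -> np.ndarray:
    """Deterministic grayscale phantom with intensities in [0, 255]."""
    if height < 64 or width < 64:
        raise ValueError("phantom dimensions must be at least 64")
    if kind == "ellipses":
        return _paint_ellipses(height, width)
    if kind == "texture":
        return _paint_texture(height, width)
    raise ValueError(f"unknown phantom kind {kind!r}; use 'ellipses' or 'texture'")


def corrupt(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply the corruption model in ``spec``; seeded and reproducible.

    Gaussian noise is added in float without clipping so sigma stays exactly
    interpretable; any clipping policy belongs to the consumer.
    """
    image = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian":
        if spec.sigma == 0.0:
            return image.copy()
        return image + spec.sigma * rng.standard_normal(image.shape)
    if spec.kind == "salt_pepper":
        out = image.copy()
        hit = rng.random(image.shape) < spec.density
        salt = rng.random(image.shape) < 0.5
        out[hit & salt] = 255.0
        out[hit & ~salt] = 0.0
        return out
    # poisson
    lam = np.clip(image, 0.0, None) / spec.scale
    return rng.poisson(lam).astype(np.float64) * spec.scale
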