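"""Soft thresholding and noise-level estimation for wavelet denoising.

The threshold policy is deliberately explicit: the universal (VisuShrink)
rule t = sigma * sqrt(2 ln n) with a MAD-based sigma estimate is the default,
with the noise sigma either known or estimated from a highpass reference
subband, and an overall multiplier for tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThresholdRule",
    "soft_threshold",
    "mad_sigma",
    "universal_threshold",
    "resolve_threshold",
]

# conventional Donoho constant (~ Phi^-1(0.75)); MAD of N(0, s) ~= s * this
_MAD_CONSTANT = 0.6745


@dataclass(frozen=True)
class ThresholdRule:
    """Shrinkage policy: which threshold, and where sigma comes from.

    rule
        ``"universal"`` for t = sigma*sqrt(2 ln n), or ``"fixed"`` for an
        explicit ``fixed_value``.
    sigma_mode
        ``"known"`` (use ``sigma_value``) or ``"mad"`` (robust estimate from
        a reference detail subband).
    multiplier
        Scales whichever threshold was resolved; 1.0 by default.
    """

    rule: str = "universal"
    sigma_mode: str = "mad"
    sigma_value: float | None = None
    multiplier: float = 1.0
    fixed_value: float | None = None

    def __post_init__(self):
        if self.rule not in ("universal", "fixed"):
            raise ValueError(f"unknown threshold rule {self.rule!r}")
        if self.sigma_mode not in ("known", "mad"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if self.sigma_value is not None and self.sigma_value < 0:
            raise ValueError("sigma_value must be nonnegative")
        if self.fixed_value is not None and self.fixed_value < 0:
            raise ValueError("fixed_value must be nonnegative")


def soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    """Elementwise sign(x) * max(|x| - t, 0)."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def mad_sigma(detail: np.ndarray) -> float:
    """Robust noise-sigma estimate median(|detail|) / 0.6745."""
    detail = np.asarray(detail)
    if detail.size == 0:
        raise ValueError("cannot estimate sigma from an empty subband")
    return float(np.median(np.abs(detail)) / _MAD_CONSTANT)


def universal_threshold(sigma: float, n: int) -> float:
    """VisuShrink threshold sigma * sqrt(2 ln n) for n coefficients."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    return float(sigma * math.sqrt(2.0 * math.log(n)))


def resolve_threshold(
    rule: ThresholdRule,
    subband: np.ndarray,
    reference_detail: np.ndarray | None = None,
) -> float:
    """Compute the threshold a :class:`ThresholdRule` prescribes for ``subband``.

    For the universal rule, n is the pixel count of the plane being
    thresholded; with ``sigma_mode="mad"`` the sigma estimate comes from
    ``reference_detail`` (a level-1 diagonal subband, typically), falling
    back to the subband itself if no reference is given.
    """
    subband = np.asarray(subband)
    if rule.rule == "fixed":
        if rule.fixed_value is None:
            raise ValueError("fixed rule requires fixed_value")
        return rule.fixed_value * rule.multiplier
    if rule.sigma_mode == "known":
        if rule.sigma_value is None:
            raise ValueError("sigma_mode='known' requires sigma_value")
        sigma = rule.sigma_value
    else:
        ref = subband if reference_detail is None else reference_detail
        sigma = mad_sigma(ref)
    return universal_threshold(sigma, subband.size) * rule.multiplier
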