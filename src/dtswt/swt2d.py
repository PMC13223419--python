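"""Forward and inverse 2-D stationary (undecimated, à-trous) wavelet transform.

The transform is computed with PyWavelets' ``swt2``/``iswt2`` (periodic
boundary extension, à-trous filter upsampling) and repackaged into a
level-1-first container.  Orientation convention: the *horizontal* detail
plane is the one produced by highpass filtering along the row axis (axis 0),
i.e. the plane that responds to horizontal edges; *vertical* is highpass
along columns; *diagonal* is highpass along both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = ["PadRecord", "SWTCoeffs", "pad_to_multiple", "swt2_forward", "swt2_inverse"]


@dataclass(frozen=True)
class PadRecord:
    """Bookkeeping to undo reflect-padding applied before a transform."""

    original_height: int
    original_width: int
    pad_top: int = 0
    pad_bottom: int = 0
    pad_left: int = 0
    pad_right: int = 0

    def crop(self, image: np.ndarray) -> np.ndarray:
        """Remove the recorded padding, restoring the original extent."""
        h = self.pad_top + self.original_height
        w = self.pad_left + self.original_width
        return image[self.pad_top : h, self.pad_left : w]


@dataclass
class SWTCoeffs:
    """Undecimated decomposition: approximation plus per-level detail planes.

    ``details[j]`` holds the level-(j+1) ``(horizontal, vertical, diagonal)``
    planes, finest level first; every plane has the (padded) input shape.
    """

    approx: np.ndarray
    details: list  # [(H, V, D)] for levels 1..L
    level: int
    wavelet: str
    pad_record: PadRecord | None = field(default=None)

    def validate(self) -> None:
        if self.level < 1 or len(self.details) != self.level:
            raise ValueError("level must be >= 1 and match the detail list")
        shape = self.approx.shape
        for planes in self.details:
            if len(planes) != 3 or any(p.shape != shape for p in planes):
                raise ValueError("all coefficient planes must share one shape")
        if shape[0] % 2**self.level or shape[1] % 2**self.level:
            raise ValueError("padded dimensions must be divisible by 2^level")


def pad_to_multiple(image: np.ndarray, multiple: int) -> tuple[np.ndarray, PadRecord]:
    """Reflect-pad ``image`` so both dimensions are multiples of ``multiple``.

    Padding is split as evenly as possible between opposite edges (symmetric
    reflection, no edge repeat where possible); the returned
    :class:`PadRecord` inverts it exactly via :meth:`PadRecord.crop`.
    """
    if multiple < 1:
        raise ValueError("multiple must be a positive integer")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    h, w = image.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    rec = PadRecord(h, w, ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
    if ph or pw:
        # 'reflect' needs dim >= 2 when padding; fall back to 'edge' for 1-px dims
        mode = "reflect" if min(h, w) > 1 else "edge"
        image = np.pad(
            image,
            ((rec.pad_top, rec.pad_bottom), (rec.pad_left, rec.pad_right)),
            mode=mode,
        )
    return image, rec


def swt2_forward(image: np.ndarray, wavelet: str = "db4", levels: int = 5) -> SWTCoeffs:
    """Undecimated 2-D wavelet decomposition over ``levels`` scales.

    Raises if the image dimensions are not divisible by ``2**levels``; use
    :func:`pad_to_multiple` first.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h, w = image.shape
    if h % 2**levels or w % 2**levels:
        raise ValueError(
            f"image shape {image.shape} not divisible by 2^{levels}; "
            "pad with pad_to_multiple first"
        )
    coeffs = pywt.swt2(image, wavelet, level=levels, trim_approx=True, norm=False)
    # pywt returns [approx, coarsest .. finest]; store finest (level 1) first.
    details = [tuple(np.asarray(p) for p in planes) for planes in coeffs[:0:-1]]
    return SWTCoeffs(
        approx=np.asarray(coeffs[0]),
        details=details,
        level=levels,
        wavelet=wavelet,
    )


def swt2_inverse(coeffs: SWTCoeffs) -> np.ndarray:
    """Reconstruct the image from an :class:`SWTCoeffs`; exact left inverse."""
    coeffs.validate()
    packed = [coeffs.approx] + [tuple(planes) for planes in coeffs.details[::-1]]
    return np.asarray(pywt.iswt2(packed, coeffs.wavelet, norm=False))
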