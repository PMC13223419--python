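"""Grayscale image reading and writing (PNG/TIFF/JPEG)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["GrayImage", "read_image", "write_image"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D float intensity array with its declared peak value."""

    data: np.ndarray
    peak: float


def read_image(path) -> GrayImage:
    """Read a PNG/TIFF/JPEG as grayscale float64 with its recorded peak.

    8-bit sources record peak 255, 16-bit sources 65535.  RGB(A) inputs are
    converted with the luminance weights (0.299, 0.587, 0.114).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise ValueError(f"could not decode image {path}: {exc}") from exc
    if np.issubdtype(arr.dtype, np.integer):
        peak = float(np.iinfo(arr.dtype).max)
    else:
        peak = float(arr.max()) if arr.size else 1.0
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"unsupported image layout with shape {arr.shape}: {path}")
    return GrayImage(arr, peak)


def write_image(path, image: np.ndarray, peak: float = 255.0) -> None:
    """Write ``image`` as 8-bit (peak <= 255) or 16-bit PNG/TIFF."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    dtype = np.uint8 if peak <= 255 else np.uint16
    out = np.clip(np.rint(image), 0, peak).astype(dtype)
    iio.imwrite(Path(path), out)
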