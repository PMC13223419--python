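"""Real 2-D dual-tree DWT: two parallel decimated wavelet trees.

Each tree is a separable orthonormal DWT (periodic boundaries); the trees use
filter pairs offset by a (half-)sample delay, which is what buys the combined
transform its near shift invariance and directional selectivity.  Stored
coefficients are scaled by 1/sqrt(2) per tree so the two trees jointly form a
tight frame (total coefficient energy equals image energy); reconstruction
averages the two per-tree inverses.

Subband indexing follows the ``W{j}{s}`` convention with j the tree and s the
orientation: s=1 is highpass along the row axis (responds to horizontal
edges), s=2 is highpass along the column axis (vertical edges), s=3 is
highpass along both (diagonal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wavelet_filters import (
    DualTreeFilterSet,
    analyze_periodic,
    get_dualtree_filters,
    synthesize_periodic,
)

__all__ = [
    "DualTreeCoeffs",
    "dualtree2_forward",
    "dualtree2_inverse",
    "ORIENTATION_NAMES",
    "HORIZONTAL_SENSITIVE_S",
]

#: orientation index -> name (s = 1, 2, 3)
ORIENTATION_NAMES = {1: "horizontal", 2: "vertical", 3: "diagonal"}

#: the s-indices whose subbands respond to horizontal edges (pure + diagonal)
HORIZONTAL_SENSITIVE_S = (1, 3)

_SQRT2 = math.sqrt(2.0)


@dataclass
class DualTreeCoeffs:
    """Dual-tree coefficients ``W{j}{s}`` for trees j in {1,2}.

    ``highpass[(level, tree, s)]`` maps to the subband at that level (shape
    ``(H/2^level, W/2^level)``); ``lowpass[tree]`` holds the two final
    scaling subbands.
    """

    highpass: dict
    lowpass: dict
    levels: int
    source_shape: tuple

    def n_coefficients(self) -> int:
        return sum(p.size for p in self.highpass.values()) + sum(
            p.size for p in self.lowpass.values()
        )

    def validate(self) -> None:
        if sorted(self.lowpass) != [1, 2]:
            raise ValueError("expected exactly two lowpass planes (trees 1 and 2)")
        h, w = self.source_shape
        for lev in range(1, self.levels + 1):
            expect = (h >> lev, w >> lev)
            for tree in (1, 2):
                for s in (1, 2, 3):
                    key = (lev, tree, s)
                    if key not in self.highpass:
                        raise ValueError(f"missing subband {key}")
                    if self.highpass[key].shape != expect:
                        raise ValueError(
                            f"subband {key} has shape {self.highpass[key].shape}, "
                            f"expected {expect}"
                        )
        expect = (h >> self.levels, w >> self.levels)
        for tree in (1, 2):
            if self.lowpass[tree].shape != expect:
                raise ValueError("lowpass plane shape inconsistent with levels")


def _tree_banks(filters: DualTreeFilterSet, tree: int):
    if tree == 1:
        return filters.first_stage_tree1, filters.qshift_tree1
    return filters.first_stage_tree2, filters.qshift_tree2


def dualtree2_forward(
    image: np.ndarray,
    levels: int = 1,
    filters: DualTreeFilterSet | None = None,
) -> DualTreeCoeffs:
    """Decompose ``image`` into dual-tree subbands over ``levels`` scales."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h, w = image.shape
    if h % 2**levels or w % 2**levels:
        raise ValueError(
            f"image shape {image.shape} not divisible by 2^{levels}"
        )
    if filters is None:
        filters = get_dualtree_filters()

    highpass: dict = {}
    lowpass: dict = {}
    for tree in (1, 2):
        first, qshift = _tree_banks(filters, tree)
        lo = image
        for lev in range(1, levels + 1):
            bank = first if lev == 1 else qshift
            row_lo, row_hi = analyze_periodic(lo, bank, axis=0)
            ll, lh = analyze_periodic(row_lo, bank, axis=1)
            hl, hh = analyze_periodic(row_hi, bank, axis=1)
            highpass[(lev, tree, 1)] = hl / _SQRT2  # highpass along rows
            highpass[(lev, tree, 2)] = lh / _SQRT2  # highpass along columns
            highpass[(lev, tree, 3)] = hh / _SQRT2  # highpass along both
            lo = ll
        lowpass[tree] = lo / _SQRT2
    return DualTreeCoeffs(highpass, lowpass, levels, (h, w))


def dualtree2_inverse(
    coeffs: DualTreeCoeffs, filters: DualTreeFilterSet | None = None
) -> np.ndarray:
    """Reconstruct the image: per-tree synthesis, then the two-tree average."""
    coeffs.validate()
    if filters is None:
        filters = get_dualtree_filters()
    recon = np.zeros(coeffs.source_shape)
    for tree in (1, 2):
        first, qshift = _tree_banks(filters, tree)
        lo = coeffs.lowpass[tree] * _SQRT2
        for lev in range(coeffs.levels, 0, -1):
            bank = first if lev == 1 else qshift
            hl = coeffs.highpass[(lev, tree, 1)] * _SQRT2
            lh = coeffs.highpass[(lev, tree, 2)] * _SQRT2
            hh = coeffs.highpass[(lev, tree, 3)] * _SQRT2
            row_lo = synthesize_periodic(lo, lh, bank, axis=1)
            row_hi = synthesize_periodic(hl, hh, bank, axis=1)
            lo = synthesize_periodic(row_lo, row_hi, bank, axis=0)
        recon += lo
    return recon / 2.0
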