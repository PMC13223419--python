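"""Orthonormal filter banks for the stationary and dual-tree wavelet transforms.

Tap tables are package constants.  ``analysis_lowpass`` holds the scaling
coefficients h[k] normalised so that ``sum(h) == sqrt(2)``; the analysis step
is the circular correlation ``y[n] = sum_k h[k] x[(2n + k) mod N]`` and the
synthesis step is its adjoint, so perfect reconstruction is equivalent to the
double-shift orthonormality of h.  The highpass is the quadrature-mirror
alternation ``g[n] = (-1)^n h[L-1-n]`` and the synthesis filters are the
time-reversed analysis filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FilterBank",
    "DualTreeFilterSet",
    "get_wavelet_filters",
    "get_dualtree_filters",
    "analyze_periodic",
    "synthesize_periodic",
]

# Daubechies-4 scaling coefficients (8 taps, orthonormal, sum = sqrt 2).
_DB4_LO = np.array(
    [
        2.30377813308896506328e-01,
        7.14846570552915672181e-01,
        6.30880767929858921050e-01,
        -2.79837694168598542788e-02,
        -1.87034811719093085891e-01,
        3.08413818355607639854e-02,
        3.28830116668851965556e-02,
        -1.05974017850690317016e-02,
    ]
)

# Farras nearly-symmetric 10-tap lowpass (first stage of the dual tree).
_FARRAS_LO = np.array(
    [
        0.0,
        -0.08838834764832,
        0.08838834764832,
        0.69587998903400,
        0.69587998903400,
        0.08838834764832,
        -0.08838834764832,
        0.01122679215254,
        0.01122679215254,
        0.0,
    ]
)

# Kingsbury q-shift 10-tap lowpass (levels >= 2 of the dual tree), refined to
# machine-precision double-shift orthonormality (the widely printed 8-decimal
# table is orthonormal only to ~8e-9).
_QSHIFT10_LO = np.array(
    [
        3.51638376241868861e-02,
        0.0,
        -8.83294206455169650e-02,
        2.33890319297875515e-01,
        7.60272368490486627e-01,
        5.87518298725480004e-01,
        0.0,
        -1.14301841119417102e-01,
        0.0,
        0.0,
    ]
)


def _qmf(lowpass: np.ndarray) -> np.ndarray:
    """Quadrature-mirror highpass: g[n] = (-1)^n h[L-1-n]."""
    g = lowpass[::-1].copy()
    g[1::2] *= -1.0
    return g


@dataclass(frozen=True)
class FilterBank:
    """A two-channel orthonormal analysis/synthesis filter bank."""

    analysis_lowpass: np.ndarray
    analysis_highpass: np.ndarray
    synthesis_lowpass: np.ndarray
    synthesis_highpass: np.ndarray

    @classmethod
    def from_lowpass(cls, lowpass) -> "FilterBank":
        lo = np.asarray(lowpass, dtype=np.float64)
        if lo.ndim != 1 or lo.size == 0:
            raise ValueError("lowpass must be a nonempty 1-D tap sequence")
        hi = _qmf(lo)
        return cls(
            analysis_lowpass=lo,
            analysis_highpass=hi,
            synthesis_lowpass=lo[::-1].copy(),
            synthesis_highpass=hi[::-1].copy(),
        )


@dataclass(frozen=True)
class DualTreeFilterSet:
    """Filters for the two parallel trees of the dual-tree DWT.

    The first-stage pair differs by an integer one-sample delay (tree 2's
    lowpass is the one-sample shift of tree 1's); deeper levels use a q-shift
    pair whose lowpass filters are time reverses of each other, realising the
    half-sample delay between the trees.
    """

    first_stage_tree1: FilterBank
    first_stage_tree2: FilterBank
    qshift_tree1: FilterBank
    qshift_tree2: FilterBank


_WAVELETS = {"db4": _DB4_LO}


def get_wavelet_filters(name: str) -> FilterBank:
    """Return the orthonormal filter bank for a named wavelet.

    Parameters
    ----------
    name
        Wavelet identifier; currently ``"db4"``.
    """
    try:
        lo = _WAVELETS[name]
    except KeyError:
        raise ValueError(
            f"unsupported wavelet {name!r}; supported: {sorted(_WAVELETS)}"
        ) from None
    return FilterBank.from_lowpass(lo)


def get_dualtree_filters(variant: str = "farras+qshift10") -> DualTreeFilterSet:
    """Return the dual-tree filter set for a named variant.

    The default ``"farras+qshift10"`` uses the Farras nearly-symmetric 10-tap
    pair at the first stage and the 10-tap q-shift pair at deeper levels.
    """
    if variant != "farras+qshift10":
        raise ValueError(
            f"unsupported dual-tree filter variant {variant!r}; "
            "supported: ['farras+qshift10']"
        )
    t1 = FilterBank.from_lowpass(_FARRAS_LO)
    # One-sample delay of tree 1 (the trailing zero keeps it inside 10 taps).
    t2 = FilterBank.from_lowpass(np.roll(_FARRAS_LO, 1))
    q1 = FilterBank.from_lowpass(_QSHIFT10_LO)
    q2 = FilterBank.from_lowpass(_QSHIFT10_LO[::-1])
    return DualTreeFilterSet(t1, t2, q1, q2)


def _circ_correlate(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Circular correlation y[n] = sum_k taps[k] x[(n + k) mod N] along axis."""
    n = x.shape[axis]
    h = np.zeros(n)
    # Wrap taps mod n so short signals remain well defined.
    for k, v in enumerate(taps):
        h[k % n] += v
    return np.fft.irfft(
        np.fft.rfft(x, axis=axis) * np.conj(np.fft.rfft(h)).reshape(
            [-1 if a == axis % x.ndim else 1 for a in range(x.ndim)]
        ),
        n=n,
        axis=axis,
    )


def _circ_convolve(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Circular convolution (adjoint of :func:`_circ_correlate`) along axis."""
    n = x.shape[axis]
    h = np.zeros(n)
    for k, v in enumerate(taps):
        h[k % n] += v
    return np.fft.irfft(
        np.fft.rfft(x, axis=axis) * np.fft.rfft(h).reshape(
            [-1 if a == axis % x.ndim else 1 for a in range(x.ndim)]
        ),
        n=n,
        axis=axis,
    )


def _even_slice(ndim: int, axis: int) -> tuple:
    sl = [slice(None)] * ndim
    sl[axis] = slice(0, None, 2)
    return tuple(sl)


def analyze_periodic(x: np.ndarray, bank: FilterBank, axis: int = -1):
    """One level of periodic two-channel analysis along ``axis``.

    Returns ``(lowpass, highpass)`` each of half length; the signal length
    along ``axis`` must be even.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[axis] % 2:
        raise ValueError("signal length must be even for dyadic analysis")
    sl = _even_slice(x.ndim, axis % x.ndim)
    lo = _circ_correlate(x, bank.analysis_lowpass, axis)[sl]
    hi = _circ_correlate(x, bank.analysis_highpass, axis)[sl]
    return lo, hi


def synthesize_periodic(
    lo: np.ndarray, hi: np.ndarray, bank: FilterBank, axis: int = -1
) -> np.ndarray:
    """Inverse of :func:`analyze_periodic` (adjoint, exact for orthonormal banks)."""
    lo = np.asarray(lo, dtype=np.float64)
    hi = np.asarray(hi, dtype=np.float64)
    if lo.shape != hi.shape:
        raise ValueError("lowpass/highpass subbands must share a shape")
    ax = axis % lo.ndim
    shape = list(lo.shape)
    shape[ax] *= 2
    up_lo = np.zeros(shape)
    up_hi = np.zeros(shape)
    sl = _even_slice(lo.ndim, ax)
    up_lo[sl] = lo
    up_hi[sl] = hi
    return _circ_convolve(up_lo, bank.analysis_lowpass, axis) + _circ_convolve(
        up_hi, bank.analysis_highpass, axis
    )
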