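import numpy as np
import pytest
import pywt

from dtswt.dualtree2d import (
    HORIZONTAL_SENSITIVE_S,
    dualtree2_forward,
    dualtree2_inverse,
)
from dtswt.synthetic import make_phantom


def test_structure_and_coefficient_count(rng):
    x = rng.standard_normal((64, 64))
    c = dualtree2_forward(x, 1)
    assert sorted(c.highpass) == [(1, t, s) for t in (1, 2) for s in (1, 2, 3)]
    assert all(p.shape == (32, 32) for p in c.highpass.values())
    assert all(c.lowpass[t].shape == (32, 32) for t in (1, 2))
    assert c.n_coefficients() == 2 * 64 * 64


def test_tight_frame_energy(rng):
    x = rng.standard_normal((64, 64)) * 50
    c = dualtree2_forward(x, 1)
    total = sum((p**2).sum() for p in c.highpass.values()) + sum(
        (p**2).sum() for p in c.lowpass.values()
    )
    assert abs(total - (x**2).sum()) / (x**2).sum() < 1e-6


@pytest.mark.parametrize("shape", [(32, 32), (64, 64), (128, 64)])
@pytest.mark.parametrize("levels", [1, 2])
def test_roundtrip_identity(rng, shape, levels):
    for _ in range(20):
        x = rng.standard_normal(shape) * 100
        c = dualtree2_forward(x, levels)
        assert np.abs(dualtree2_inverse(c) - x).max() < 1e-9


def test_zero_coefficients_reconstruct_zero(rng):
    c = dualtree2_forward(rng.standard_normal((32, 32)), 1)
    for k in c.highpass:
        c.highpass[k] = np.zeros_like(c.highpass[k])
    for t in c.lowpass:
        c.lowpass[t] = np.zeros_like(c.lowpass[t])
    assert np.abs(dualtree2_inverse(c)).max() == 0.0


def test_linearity(rng):
    x = rng.standard_normal((64, 64))
    y = rng.standard_normal((64, 64))
    a, b = 2.5, -1.25
    cx = dualtree2_forward(x, 2)
    cy = dualtree2_forward(y, 2)
    cz = dualtree2_forward(a * x + b * y, 2)
    for k in cz.highpass:
        assert np.abs(cz.highpass[k] - a * cx.highpass[k] - b * cy.highpass[k]).max() < 1e-9
    for t in (1, 2):
        assert np.abs(cz.lowpass[t] - a * cx.lowpass[t] - b * cy.lowpass[t]).max() < 1e-9


def test_orientation_selectivity_horizontal_edge():
    img = np.zeros((64, 64))
    img[32:, :] = 100.0
    c = dualtree2_forward(img, 1)
    energy = {s: sum((c.highpass[(1, t, s)] ** 2).sum() for t in (1, 2)) for s in (1, 2, 3)}
    sensitive = sum(energy[s] for s in HORIZONTAL_SENSITIVE_S)
    assert sensitive > 0.8 * sum(energy.values())


def _subband_energy_vector_dt(x, levels=2):
    c = dualtree2_forward(x, levels)
    keys = sorted(c.highpass)
    return np.array([(c.highpass[k] ** 2).sum() for k in keys] +
                    [(c.lowpass[t] ** 2).sum() for t in (1, 2)])


def _subband_energy_vector_dwt(x, levels=2):
    coeffs = pywt.wavedec2(x, "db4", mode="periodization", level=levels)
    vec = [(coeffs[0] ** 2).sum()]
    for planes in coeffs[1:]:
        vec.extend((p**2).sum() for p in planes)
    return np.array(vec)


def test_near_shift_invariance_beats_single_tree():
    """Per-subband energies move less under a 1-px shift than a decimated DWT's."""
    x = make_phantom(64, 64, "texture")
    xs = np.roll(x, (1, 1), axis=(0, 1))

    e_dt, e_dt_s = _subband_energy_vector_dt(x), _subband_energy_vector_dt(xs)
    e_dw, e_dw_s = _subband_energy_vector_dwt(x), _subband_energy_vector_dwt(xs)
    rel_dt = np.linalg.norm(e_dt - e_dt_s) / np.linalg.norm(e_dt)
    rel_dw = np.linalg.norm(e_dw - e_dw_s) / np.linalg.norm(e_dw)
    assert rel_dt < rel_dw


def test_invalid_inputs_raise(rng):
    with pytest.raises(ValueError, match="divisible"):
        dualtree2_forward(np.zeros((30, 32)), 2)
    c = dualtree2_forward(rng.standard_normal((32, 32)), 1)
    c.highpass[(1, 1, 1)] = c.highpass[(1, 1, 1)][:8, :8]
    with pytest.raises(ValueError, match="shape"):
        dualtree2_inverse(c)
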