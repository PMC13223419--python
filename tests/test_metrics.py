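import math

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from dtswt.metrics import compute_metrics, fsim, infer_peak, nmse, psnr, ssim
from dtswt.synthetic import NoiseSpec, corrupt

from _oracles import fsim_loop, ssim_loop


def test_psnr_closed_form_and_identity(rng):
    # MSE exactly 1 at peak 255 -> 20 log10(255)
    assert psnr(np.zeros((8, 8)), np.ones((8, 8)), 255.0) == pytest.approx(
        48.1308, abs=1e-4
    )
    x = rng.random((16, 16))
    assert psnr(x, x) == math.inf
    y = x + rng.standard_normal((16, 16))
    c = 17.0
    assert psnr(x, y, 255.0) == pytest.approx(psnr(c * x, c * y, c * 255.0))
    with pytest.raises(ValueError, match="shape"):
        psnr(x, y[:8, :8])


def test_nmse_cases(rng):
    x = rng.random((16, 16))
    assert nmse(x, x) == 0.0
    assert nmse(np.ones(2), np.zeros(2)) == 1.0
    y = x + 0.1
    assert nmse(3.0 * x, 3.0 * y) == pytest.approx(nmse(x, y))
    with pytest.raises(ValueError, match="zero"):
        nmse(np.zeros(4), np.ones(4))


def test_ssim_identity_and_symmetry(rng):
    x = rng.random((32, 32)) * 255
    y = x + rng.standard_normal((32, 32)) * 10
    assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)
    assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)
    with pytest.raises(ValueError):
        ssim(x[:8, :8], y[:8, :8])


def test_ssim_matches_loop_oracle(rng):
    for _ in range(10):
        x = rng.random((64, 64)) * 255
        y = np.clip(x + rng.standard_normal((64, 64)) * 25, 0, 255)
        assert ssim(x, y, 255.0) == pytest.approx(ssim_loop(x, y, 255.0), abs=1e-7)


def test_ssim_matches_skimage(rng):
    x = rng.random((96, 96)) * 255
    y = np.clip(x + rng.standard_normal((96, 96)) * 15, 0, 255)
    expected = structural_similarity(
        x, y, gaussian_weights=True, sigma=1.5, use_sample_covariance=False, data_range=255.0
    )
    assert ssim(x, y, 255.0) == pytest.approx(expected, abs=1e-9)


def test_fsim_identity_and_symmetry(ellipse_phantom, rng):
    assert fsim(ellipse_phantom, ellipse_phantom) == pytest.approx(1.0, abs=1e-12)
    noisy = corrupt(ellipse_phantom, NoiseSpec("gaussian", sigma=20.0, seed=1))
    assert fsim(ellipse_phantom, noisy) == pytest.approx(
        fsim(noisy, ellipse_phantom), abs=1e-10
    )
    with pytest.raises(ValueError):
        fsim(np.zeros((16, 16)), np.zeros((16, 16)))


def test_fsim_monotone_degradation(ellipse_phantom):
    small = corrupt(ellipse_phantom, NoiseSpec("gaussian", sigma=5.0, seed=3))
    large = corrupt(ellipse_phantom, NoiseSpec("gaussian", sigma=50.0, seed=3))
    assert fsim(ellipse_phantom, small) > fsim(ellipse_phantom, large)


def test_fsim_matches_loop_oracle(rng):
    for _ in range(3):
        x = rng.random((64, 64)) * 255
        y = np.clip(x + rng.standard_normal((64, 64)) * 25, 0, 255)
        assert fsim(x, y, 255.0) == pytest.approx(fsim_loop(x, y, 255.0), abs=1e-7)


def test_psnr_and_nmse_rank_identically(ellipse_phantom):
    pairs = [
        corrupt(ellipse_phantom, NoiseSpec("gaussian", sigma=s, seed=i))
        for i, s in enumerate(np.linspace(2, 60, 20))
    ]
    psnrs = [psnr(ellipse_phantom, p) for p in pairs]
    nmses = [nmse(ellipse_phantom, p) for p in pairs]
    assert list(np.argsort(psnrs)) == list(np.argsort(nmses)[::-1])


def test_report_and_peak_inference(ellipse_phantom):
    assert infer_peak(np.array([[1, 2]], dtype=np.uint8)) == 255.0
    assert infer_peak(np.array([[1.0, 7.5]])) == 7.5
    noisy = corrupt(ellipse_phantom, NoiseSpec("gaussian", sigma=20.0, seed=0))
    report = compute_metrics(ellipse_phantom, noisy, 255.0)
    assert report.psnr == pytest.approx(psnr(ellipse_phantom, noisy, 255.0))
    same = compute_metrics(ellipse_phantom, ellipse_phantom, 255.0)
    assert same.to_dict()["psnr"] == "inf"
    assert same.ssim == pytest.approx(1.0) and same.nmse == 0.0
    assert same.fsim == pytest.approx(1.0)
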