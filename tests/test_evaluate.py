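"""Evaluation battery vs brute-force oracles."""

import numpy as np
import pytest
from skimage.metrics import peak_signal_noise_ratio

from gliomap.evaluate import (dice_coefficient, dice_vs_threshold,
                              density_regression, image_quality,
                              residual_error, voi_statistics, volume_expansion,
                              expansion_vs_threshold)


# ---------------------------------------------------------------------- dice

def dice_oracle(a, b):
    """Set-based Sørensen-Dice on explicit voxel index sets."""
    A = {tuple(i) for i in np.argwhere(a)}
    B = {tuple(i) for i in np.argwhere(b)}
    if not A and not B:
        return 1.0
    return 2 * len(A & B) / (len(A) + len(B))


def test_dice_matches_set_oracle_exactly(rng):
    for _ in range(10):
        a = rng.random((10, 10, 10)) > 0.6
        b = rng.random((10, 10, 10)) > 0.6
        assert dice_coefficient(a, b) == dice_oracle(a, b)


def test_dice_counting_example():
    a = np.zeros(12, bool)
    b = np.zeros(12, bool)
    a[:4] = True          # |A| = 4
    b[1:7] = True         # |B| = 6, overlap = 3
    assert dice_coefficient(a, b) == pytest.approx(0.6)


def test_dice_empty_set_conventions():
    z = np.zeros((3, 3), bool)
    o = np.ones((3, 3), bool)
    assert dice_coefficient(z, z) == 1.0
    assert dice_coefficient(z, o) == 0.0


def test_dice_curve_identical_volumes_and_above_max(rng):
    vol = rng.uniform(0, 3, (16, 16, 4))
    curve = dice_vs_threshold(vol, vol, [1.0, 1.5, 2.0, 99.0])
    assert [d for _, d in curve] == [1.0] * 4  # incl. both-empty at t=99
    with pytest.raises(ValueError):
        dice_vs_threshold(vol, vol, [0.0])


# ------------------------------------------------------------------ residual

def test_residual_identical_is_zero(subject, rng):
    vol = rng.uniform(0, 3, subject.brain_mask.shape)
    assert residual_error(vol, vol, subject.brain_mask) == (0.0, 0.0, 0.0)


def test_residual_constant_encoded_offset():
    truth = np.full((5, 5, 5), 1.0)
    gliomap = truth + 5.1 / 51.0  # constant offset of 5.1 in 8-bit units
    mean, sd, signed = residual_error(gliomap, truth, np.ones_like(truth, bool))
    assert mean == pytest.approx(0.1)
    assert sd == pytest.approx(0.0, abs=1e-12)
    assert signed == pytest.approx(0.1)


def test_residual_of_gaussian_noise_is_folded_normal_mean(rng):
    truth = np.full((20, 20, 25), 1.5)
    noise = rng.normal(0, 0.05, truth.shape)
    mean, _, signed = residual_error(truth + noise, truth,
                                     np.ones_like(truth, bool))
    assert mean == pytest.approx(0.05 * np.sqrt(2 / np.pi), abs=2e-3)
    assert abs(signed) < 2e-3


def test_residual_empty_mask_is_error():
    v = np.ones((2, 2, 2))
    with pytest.raises(ValueError):
        residual_error(v, v, np.zeros_like(v, bool))


# ------------------------------------------------------------- image quality

def test_psnr_closed_form_and_library_crosscheck(rng):
    truth = np.full((16, 16, 4), 100.0)
    pred = np.full((16, 16, 4), 110.0)
    psnr, snr, _ = image_quality(pred, truth)
    assert psnr == pytest.approx(10 * np.log10(255.0**2 / 100.0))  # ~28.13 dB
    assert snr == pytest.approx(10 * np.log10(100.0**2 / 10.0**2))  # 20 dB
    a = rng.uniform(0, 255, (16, 16, 4))
    b = rng.uniform(0, 255, (16, 16, 4))
    psnr_ab, _, _ = image_quality(a, b)
    assert psnr_ab == pytest.approx(peak_signal_noise_ratio(b, a, data_range=255.0))


def test_identical_volumes_give_infinite_psnr_and_unit_ssim(rng):
    vol = rng.uniform(0, 255, (16, 16, 4))
    psnr, snr, ssim = image_quality(vol, vol)
    assert np.isinf(psnr) and np.isinf(snr)
    assert ssim == 1.0


def test_ssim_below_one_for_any_difference(rng):
    vol = rng.uniform(0, 255, (16, 16, 4))
    other = vol.copy()
    other[0, 0, 0] += 30.0
    assert image_quality(other, vol)[2] < 1.0


def test_inverted_structure_has_low_ssim(rng):
    base = np.kron(rng.uniform(0, 255, (8, 8, 4)), np.ones((4, 4, 1)))
    _, _, ssim = image_quality(255.0 - base, base)
    assert ssim < 0.2


def test_psnr_decreases_with_mse(rng):
    truth = rng.uniform(0, 255, (12, 12, 4))
    small = image_quality(truth + 5.0, truth)[0]
    large = image_quality(truth + 20.0, truth)[0]
    assert large < small


def test_ssim_is_symmetric(rng):
    a = rng.uniform(0, 255, (16, 16, 4))
    b = rng.uniform(0, 255, (16, 16, 4))
    assert image_quality(a, b)[2] == pytest.approx(image_quality(b, a)[2], rel=1e-12)


# ------------------------------------------------------------------ expansion

def test_expansion_counting_oracle():
    enh = np.zeros(200, bool)
    enh[:100] = True
    lesion = np.zeros(200, bool)
    lesion[50:129] = True  # 50 inside, 29 outside
    assert volume_expansion(lesion, enh) == pytest.approx(1.29)


def test_expansion_edge_cases():
    enh = np.ones(10, bool)
    assert volume_expansion(np.zeros(10, bool), enh) == 1.0  # empty lesion
    lesion = np.zeros(10, bool)
    lesion[:3] = True
    assert volume_expansion(lesion, enh) == 1.0  # lesion subset of enhancing
    with pytest.raises(ValueError):
        volume_expansion(lesion, np.zeros(10, bool))


def test_expansion_always_at_least_one(rng):
    for _ in range(5):
        enh = rng.random(100) > 0.7
        if not enh.any():
            continue
        lesion = rng.random(100) > 0.5
        assert volume_expansion(lesion, enh) >= 1.0


def test_expansion_curve_on_volume(subject):
    tn = np.where(subject.tumor_mask, 3.0, 1.0)
    curve = expansion_vs_threshold(tn, subject.enhancing_mask, [1.5])
    expected = (subject.tumor_mask | subject.enhancing_mask).sum() \
        / subject.enhancing_mask.sum()
    assert curve[0][1] == pytest.approx(expected)


# ------------------------------------------------------------------------ VOI

def test_voi_uniform_volume():
    vol = np.full((20, 20, 20), 1.5)
    mean, sd = voi_statistics(vol, (0.0, 0.0, 0.0), (2.5, 2.5, 2.5))
    assert (mean, sd) == (1.5, 0.0)


def test_voi_half_half_mean():
    vol = np.ones((20, 20, 20))
    vol[10:] = 2.0  # half/half split at the grid midplane
    # center between voxels 9 and 10 -> position (9.5 - 9.5) * 2.5 = 0 mm
    mean, _ = voi_statistics(vol, (0.0, 0.0, 0.0), (2.5, 2.5, 2.5))
    assert mean == pytest.approx(1.5)


def test_voi_at_corner_is_error():
    vol = np.ones((20, 20, 20))
    corner_mm = (-9.5 * 2.5, -9.5 * 2.5, -9.5 * 2.5)
    with pytest.raises(ValueError):
        voi_statistics(vol, corner_mm, (2.5, 2.5, 2.5))


# ------------------------------------------------------------------ regression

def test_regression_recovers_exact_generating_line():
    density = np.linspace(0, 30000, 16)
    tn = 5.8e-5 * density + 1.0
    slope, intercept, p, r = density_regression(list(zip(tn, density)))
    assert slope == pytest.approx(5.8e-5, rel=1e-9)
    assert intercept == pytest.approx(1.0, rel=1e-9)
    assert r == pytest.approx(1.0)
    assert p < 1e-10


def test_regression_exact_line_through_three_points():
    samples = [(1.0, 0.0), (1.0, 0.0), (2.16, 20000.0)]
    slope, intercept, _, _ = density_regression(samples)
    assert slope == pytest.approx(0.058 / 1000)
    assert intercept == pytest.approx(1.0)


def test_regression_pvalue_matches_independent_fit(rng):
    density = rng.uniform(0, 30000, 16)
    tn = 5.8e-5 * density + 1.0 + rng.normal(0, 0.2, 16)
    slope, intercept, p, r = density_regression(list(zip(tn, density)))
    import statsmodels.api as sm
    fit = sm.OLS(tn, sm.add_constant(density)).fit()
    assert slope == pytest.approx(fit.params[1], rel=1e-9)
    assert p == pytest.approx(fit.pvalues[1], rel=1e-6)


def test_regression_input_validation():
    with pytest.raises(ValueError):
        density_regression([(1.0, 5.0), (1.1, 6.0)])
    with pytest.raises(ValueError):
        density_regression([(1.0, 5.0)] * 5)
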