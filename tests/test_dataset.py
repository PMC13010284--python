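"""Pair assembly, mirroring augmentation, splitting, and PNG round trips."""

import numpy as np
import pandas as pd
import pytest

from gliomap.dataset import (SourceTargetPair, build_pairs, embed_from_square,
                             export_pairs, fit_to_square, load_pairs,
                             mirror_augment, quantize_8bit, split_cohort)


def make_pair(i=0, shape=(8, 8), mirrored=False, rng=None):
    rng = rng or np.random.default_rng(i)
    return SourceTargetPair(
        subject_id=f"sub-{i:03d}", slice_index=i,
        source_rgb=rng.integers(0, 256, (*shape, 3), dtype=np.uint8),
        target=rng.integers(0, 256, shape, dtype=np.uint8), mirrored=mirrored)


@pytest.mark.parametrize("value, expected", [
    (76.5, 77), (0.49, 0), (0.5, 1), (255.4, 255), (-3.0, 0), (300.0, 255)])
def test_quantization_rounds_half_up(value, expected):
    assert quantize_8bit(np.array([value]))[0] == expected


def test_pair_count_matches_mask_slice_oracle(processed):
    frac = 0.05
    mask = processed.brain_mask
    expected = sum(mask[:, :, k].mean() >= frac for k in range(mask.shape[2]))
    pairs = build_pairs(processed, slice_axis=2, min_brain_fraction=frac)
    assert len(pairs) == expected
    assert all(p.source_rgb.dtype == np.uint8 and p.target.dtype == np.uint8
               for p in pairs)


def test_impossible_threshold_yields_empty_with_warning(processed):
    with pytest.warns(UserWarning, match="min_brain_fraction"):
        assert build_pairs(processed, min_brain_fraction=1.1) == []


def test_channel_assignment_is_t1_t2_zce(processed):
    p = build_pairs(processed, min_brain_fraction=0.05)[5]
    k = p.slice_index
    np.testing.assert_array_equal(p.source_rgb[..., 0],
                                  quantize_8bit(processed.t1w_norm[:, :, k]))
    np.testing.assert_array_equal(p.source_rgb[..., 1],
                                  quantize_8bit(processed.t2w_norm[:, :, k]))
    np.testing.assert_array_equal(p.source_rgb[..., 2],
                                  quantize_8bit(processed.zce_encoded[:, :, k]))


def test_mirror_doubles_and_is_involutive():
    pairs = [make_pair(i) for i in range(3)]
    out = mirror_augment(pairs)
    assert len(out) == 6
    assert [p.mirrored for p in out] == [False] * 3 + [True] * 3
    for orig, flipped in zip(out[:3], out[3:]):
        np.testing.assert_array_equal(flipped.source_rgb[:, ::-1], orig.source_rgb)
        np.testing.assert_array_equal(flipped.target[:, ::-1], orig.target)
    assert mirror_augment([]) == []


def test_split_is_deterministic_subject_level():
    subjects = [f"sub-{i:03d}" for i in range(81)]
    a = split_cohort(subjects, 65, seed=9)
    b = split_cohort(subjects, 65, seed=9)
    assert a == b
    assert len(a.train_subjects) == 65 and len(a.test_subjects) == 16
    assert set(a.train_subjects) | set(a.test_subjects) == set(subjects)
    assert not set(a.train_subjects) & set(a.test_subjects)
    c = split_cohort(subjects, 65, seed=10)
    assert c.train_subjects != a.train_subjects


def test_split_rejects_oversized_train():
    with pytest.raises(ValueError):
        split_cohort(["a", "b"], 2, seed=0)


def test_square_fit_pad_and_crop_roundtrip(rng):
    img = rng.integers(0, 256, (10, 14, 3), dtype=np.uint8)
    padded = fit_to_square(img, 16)
    assert padded.shape == (16, 16, 3)
    np.testing.assert_array_equal(embed_from_square(padded, (10, 14)), img)
    cropped = fit_to_square(img, 8)
    assert cropped.shape == (8, 8, 3)
    # cropping keeps the center window
    np.testing.assert_array_equal(cropped, img[1:9, 3:11])


def test_png_export_load_roundtrip(tmp_path):
    pairs = [make_pair(i) for i in range(4)] + [make_pair(9, mirrored=True)]
    manifest = export_pairs(pairs, tmp_path, "train")
    assert len(manifest) == 5
    assert (tmp_path / "manifest_train.csv").exists()
    loaded = load_pairs(tmp_path, "train")
    for a, b in zip(pairs, loaded):
        assert a.subject_id == b.subject_id and a.mirrored == b.mirrored
        np.testing.assert_array_equal(a.source_rgb, b.source_rgb)
        np.testing.assert_array_equal(a.target, b.target)


def test_pair_shape_validation():
    with pytest.raises(ValueError):
        SourceTargetPair("s", 0, np.zeros((4, 4, 3), np.uint8),
                         np.zeros((4, 5), np.uint8))
    with pytest.raises(ValueError):
        SourceTargetPair("s", 0, np.zeros((4, 4, 2), np.uint8),
                         np.zeros((4, 4), np.uint8))
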