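"""Conditional-GAN translator: configuration, determinism, learnability."""

import numpy as np
import pytest

from gliomap.dataset import SourceTargetPair
from gliomap.gan import (GanConfig, GliomapVolume, Pix2PixTranslator,
                         desk_preset, generate_gliomap, full_preset)

TINY = dict(image_size=32, generator_base_channels=8, discriminator_base_channels=8,
            n_unet_levels=2, n_discriminator_layers=1, batch_size=2, seed=0)


def affine_pairs(n=16, size=32, seed=0):
    """Synthetic task: target is the channel-mean of the source (affine map)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        # smooth random blobs so the mapping has spatial structure
        base = rng.integers(0, 256, (size // 4, size // 4, 3))
        src = np.kron(base, np.ones((4, 4, 1))).astype(np.uint8)
        tgt = src.mean(axis=-1).astype(np.uint8)
        pairs.append(SourceTargetPair(f"sub-{i % 4}", i, src, tgt))
    return pairs


def test_config_validation():
    with pytest.raises(ValueError):
        GanConfig(image_size=48).validate()
    with pytest.raises(ValueError):
        GanConfig(epochs=0).validate()
    with pytest.raises(ValueError):
        GanConfig(lambda_l1=-1.0).validate()
    desk_preset().validate()
    full_preset().validate()
    assert full_preset().image_size == 256 and full_preset().epochs == 200


def test_empty_or_mismatched_training_set_rejected():
    m = Pix2PixTranslator(**TINY, epochs=1)
    with pytest.raises(ValueError, match="empty"):
        m.fit([])
    with pytest.raises(ValueError, match="image_size"):
        m.fit(affine_pairs(2, size=16))


def test_training_is_deterministic_under_seed():
    pairs = affine_pairs(8)
    a = Pix2PixTranslator(**TINY, epochs=1).fit(pairs)
    b = Pix2PixTranslator(**TINY, epochs=1).fit(pairs)
    assert a.trace_.loss_g_adv == b.trace_.loss_g_adv
    assert a.trace_.loss_d == b.trace_.loss_d
    src = pairs[0].source_rgb
    np.testing.assert_array_equal(a.predict(src), b.predict(src))


def test_reinference_is_bit_identical():
    pairs = affine_pairs(6)
    m = Pix2PixTranslator(**TINY, epochs=1).fit(pairs)
    src = np.stack([p.source_rgb for p in pairs[:3]])
    np.testing.assert_array_equal(m.predict(src), m.predict(src))


def test_output_bounded_and_finite_on_degenerate_input():
    m = Pix2PixTranslator(**TINY, epochs=1).fit(affine_pairs(4))
    out = m.predict(np.zeros((32, 32, 3), np.uint8))
    assert np.isfinite(out).all()
    assert out.min() >= 0.0 and out.max() <= 255.0


def test_affine_task_learnability():
    """Validation residual on a deterministic affine task drops >= 2x."""
    pairs = affine_pairs(24)
    m = Pix2PixTranslator(**TINY, epochs=12).fit(pairs[:20], val_pairs=pairs[20:])
    vr = m.trace_.val_residual_tn
    assert all(np.isfinite(vr))
    assert vr[-1] < vr[0] / 2


def test_losses_finite_and_non_divergent():
    m = Pix2PixTranslator(**TINY, epochs=4).fit(affine_pairs(12))
    for series in (m.trace_.loss_g_adv, m.trace_.loss_g_l1, m.trace_.loss_d):
        assert all(np.isfinite(series))
        assert max(series) <= 10 * max(series[0], 1e-3)


def test_zero_l1_weight_is_passed_through():
    m = Pix2PixTranslator(**TINY, epochs=1, lambda_l1=0.0).fit(affine_pairs(4))
    assert m.lambda_l1 == 0.0
    assert all(np.isfinite(m.trace_.loss_g_adv))


def test_weight_save_load_roundtrip(tmp_path):
    pairs = affine_pairs(6)
    m = Pix2PixTranslator(**TINY, epochs=1).fit(pairs)
    m.save_weights(tmp_path / "w.npz")
    m2 = Pix2PixTranslator(**TINY).load_weights(tmp_path / "w.npz")
    src = pairs[0].source_rgb
    np.testing.assert_array_equal(m.predict(src), m2.predict(src))


def test_generate_gliomap_flags_collapsed_slices(processed):
    class ConstantModel:
        image_size = 64
        batch_size = 4
        min_dynamic_range = 5.0

        def predict(self, sources):
            return np.full(sources.shape[:3], 80.0)

    gm = generate_gliomap(ConstantModel(), processed)
    assert gm.failed_slices == list(range(processed.brain_mask.shape[2]))
    assert gm.encoded.shape == processed.brain_mask.shape
    np.testing.assert_allclose(gm.tn * 51.0, gm.encoded)


def test_sklearn_param_interface():
    m = Pix2PixTranslator(**TINY)
    params = m.get_params()
    assert params["image_size"] == 32
    m.set_params(epochs=3)
    assert m.epochs == 3
    assert Pix2PixTranslator.from_config(desk_preset()).config == desk_preset()
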