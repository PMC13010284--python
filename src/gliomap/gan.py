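"""Conditional GAN translating RGB MRI slices into PET-like targets.

The translator follows the pix2pix recipe: a U-Net generator G maps the
3-channel source slice to the 1-channel target, a PatchGAN discriminator D
judges (source, target) patches, and G minimizes an adversarial binary
cross-entropy term plus a strong L1 reconstruction term (weight λ, default
100) while D maximizes the adversarial term.  Optimization is Adam
(lr 2e-4, β₁ 0.5) with alternating D/G updates.

Two presets are provided: ``full_preset`` mirrors the published
configuration (256 px, 64 base channels, 200 epochs) and ``desk_preset`` is a
reduced configuration (64 px, 16 base channels, 10 epochs) sized so a full
train/infer/evaluate cycle runs in minutes on one CPU core.

Images enter the network scaled to [-1, 1]; the generator's tanh head keeps
its output in the valid range by construction, and outputs are mapped back to
the continuous 0–255 scale (decodable to tumor-to-normal units via /51).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._nn import (Adam, Conv2d, ConvTranspose2d, InstanceNorm2d, LeakyReLU,
                  ReLU, Tanh, bce_with_logits, l1_loss, F32)
from .dataset import SourceTargetPair, ProcessedSubject, fit_to_square, \
    embed_from_square, quantize_8bit
from .pet_tn import TN_SCALE

__all__ = [
    "GanConfig", "TrainingTrace", "GliomapVolume", "Pix2PixTranslator",
    "UNetGenerator", "PatchGANDiscriminator",
    "desk_preset", "full_preset", "train", "generate_gliomap",
]


@dataclass(frozen=True)
class GanConfig:
    image_size: int = 64
    generator_base_channels: int = 16
    discriminator_base_channels: int = 16
    n_unet_levels: int = 3
    n_discriminator_layers: int = 2
    lambda_l1: float = 100.0
    epochs: int = 10
    batch_size: int = 2
    learning_rate: float = 2e-4
    beta1: float = 0.5
    seed: int = 0
    device: str = "cpu"
    min_dynamic_range: float = 5.0  # 8-bit units; below this a slice is "failed"

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        s = self.image_size
        if s < 32 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 32")
        if self.n_unet_levels < 2 or 2 ** self.n_unet_levels > s:
            raise ValueError("n_unet_levels incompatible with image_size")


def desk_preset(**overrides) -> GanConfig:
    """Reduced-scale configuration that trains in minutes on one CPU."""
    return GanConfig(**{**dict(image_size=64, generator_base_channels=16,
                               discriminator_base_channels=16, n_unet_levels=3,
                               n_discriminator_layers=2, epochs=10, batch_size=2),
                        **overrides})


def full_preset(**overrides) -> GanConfig:
    """Published-scale configuration (256 px, 64 base channels, 200 epochs)."""
    return GanConfig(**{**dict(image_size=256, generator_base_channels=64,
                               discriminator_base_channels=64, n_unet_levels=7,
                               n_discriminator_layers=3, epochs=200, batch_size=1),
                        **overrides})


@dataclass
class TrainingTrace:
    epochs: list[int] = field(default_factory=list)
    loss_g_adv: list[float] = field(default_factory=list)
    loss_g_l1: list[float] = field(default_factory=list)
    loss_d: list[float] = field(default_factory=list)
    val_residual_tn: list[float] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "loss_g_adv": self.loss_g_adv,
                             "loss_g_l1": self.loss_g_l1, "loss_d": self.loss_d,
                             "val_residual_tn": self.val_residual_tn})


@dataclass
class GliomapVolume:
    """A generated PET-like volume, decodable to T/N units (pixel / 51)."""

    subject_id: str
    encoded: np.ndarray            # continuous 0–255, subject grid
    failed_slices: list[int] = field(default_factory=list)

    @property
    def tn(self) -> np.ndarray:
        return self.encoded / TN_SCALE


# ---------------------------------------------------------------------------
# networks

class UNetGenerator:
    """Encoder–decoder with skip connections; tanh output head."""

    def __init__(self, in_channels: int, out_channels: int, base_channels: int,
                 n_levels: int, rng: np.random.Generator):
        self.n_levels = n_levels
        ch = [min(base_channels * 2**i, base_channels * 8) for i in range(n_levels)]
        self.enc_conv, self.enc_norm, self.enc_act = [], [], []
        for i in range(n_levels):
            c_in = in_channels if i == 0 else ch[i - 1]
            self.enc_conv.append(Conv2d(c_in, ch[i], rng))
            self.enc_norm.append(InstanceNorm2d(ch[i]) if i > 0 else None)
            self.enc_act.append(LeakyReLU(0.2) if i > 0 else None)
        self.dec_deconv, self.dec_norm, self.dec_act = [], [], []
        for i in range(n_levels - 1, -1, -1):
            c_in = ch[i] if i == n_levels - 1 else 2 * ch[i]
            c_out = out_channels if i == 0 else ch[i - 1]
            self.dec_deconv.append(ConvTranspose2d(c_in, c_out, rng))
            self.dec_norm.append(InstanceNorm2d(c_out) if i > 0 else None)
            self.dec_act.append(ReLU())
        # dec lists are indexed by position in the decoding order (innermost first)
        self.tanh = Tanh()
        self.params = []
        for layer in (*self.enc_conv, *filter(None, self.enc_norm),
                      *self.dec_deconv, *filter(None, self.dec_norm)):
            self.params.extend(layer.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for i in range(self.n_levels):
            if i > 0:
                h = self.enc_act[i](h)
            h = self.enc_conv[i](h)
            if i > 0:
                h = self.enc_norm[i](h)
            skips.append(h)
        self._skip_channels = [s.shape[1] for s in skips]
        h = skips[-1]
        for pos, i in enumerate(range(self.n_levels - 1, -1, -1)):
            h = self.dec_act[pos](h)
            h = self.dec_deconv[pos](h)
            if i > 0:
                h = self.dec_norm[pos](h)
                h = np.concatenate([h, skips[i - 1]], axis=1)
        return self.tanh(h)

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self.n_levels
        d = self.tanh.backward(dy)
        dskips: list = [None] * L
        # decoder, reversed: positions L-1 .. 0 correspond to levels 0 .. L-1
        for pos in range(L - 1, -1, -1):
            i = L - 1 - pos
            if i > 0:
                c = self.dec_deconv[pos].c_out
                d_main, d_sk = d[:, :c], d[:, c:]
                dskips[i - 1] = d_sk if dskips[i - 1] is None else dskips[i - 1] + d_sk
                d = self.dec_norm[pos].backward(d_main)
            d = self.dec_deconv[pos].backward(d)
            d = self.dec_act[pos].backward(d)
        dskips[L - 1] = d if dskips[L - 1] is None else dskips[L - 1] + d
        # encoder, reversed
        for i in range(L - 1, 0, -1):
            g = self.enc_norm[i].backward(dskips[i])
            g = self.enc_conv[i].backward(g)
            g = self.enc_act[i].backward(g)
            dskips[i - 1] = dskips[i - 1] + g
        return self.enc_conv[0].backward(dskips[0])


class PatchGANDiscriminator:
    """Convolutional patch classifier on concatenated (source, target)."""

    def __init__(self, in_channels: int, base_channels: int, n_layers: int,
                 rng: np.random.Generator):
        layers: list = [Conv2d(in_channels, base_channels, rng), LeakyReLU(0.2)]
        c = base_channels
        for i in range(1, n_layers):
            layers += [Conv2d(c, min(2 * c, 8 * base_channels), rng),
                       InstanceNorm2d(min(2 * c, 8 * base_channels)), LeakyReLU(0.2)]
            c = min(2 * c, 8 * base_channels)
        layers += [Conv2d(c, min(2 * c, 8 * base_channels), rng, stride=1),
                   InstanceNorm2d(min(2 * c, 8 * base_channels)), LeakyReLU(0.2)]
        c = min(2 * c, 8 * base_channels)
        layers += [Conv2d(c, 1, rng, stride=1)]
        self.layers = layers
        self.params = [p for lay in layers for p in getattr(lay, "params", [])]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay(x)
        return x

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# translator

def _to_net(img: np.ndarray) -> np.ndarray:
    return (np.asarray(img, dtype=F32) / 127.5 - 1.0).astype(F32)


def _from_net(y: np.ndarray) -> np.ndarray:
    return (y.astype(np.float64) + 1.0) * 127.5


class Pix2PixTranslator(BaseEstimator):
    """Sklearn-style estimator wrapping the conditional-GAN translator.

    ``fit(pairs)`` trains generator and discriminator on a list of
    :class:`SourceTargetPair`; ``predict(sources)`` maps 8-bit RGB slices to
    continuous 0–255 PET-like slices.

    Attributes
    ----------
    generator_ : UNetGenerator
    discriminator_ : PatchGANDiscriminator
    trace_ : TrainingTrace
        Per-epoch generator/discriminator losses and validation residual
        error in T/N units.
    """

    def __init__(self, image_size: int = 64, generator_base_channels: int = 16,
                 discriminator_base_channels: int = 16, n_unet_levels: int = 3,
                 n_discriminator_layers: int = 2, lambda_l1: float = 100.0,
                 epochs: int = 10, batch_size: int = 2, learning_rate: float = 2e-4,
                 beta1: float = 0.5, seed: int = 0, device: str = "cpu",
                 min_dynamic_range: float = 5.0):
        self.image_size = image_size
        self.generator_base_channels = generator_base_channels
        self.discriminator_base_channels = discriminator_base_channels
        self.n_unet_levels = n_unet_levels
        self.n_discriminator_layers = n_discriminator_layers
        self.lambda_l1 = lambda_l1
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.seed = seed
        self.device = device
        self.min_dynamic_range = min_dynamic_range

    @classmethod
    def from_config(cls, config: GanConfig) -> "Pix2PixTranslator":
        return cls(**asdict(config))

    @property
    def config(self) -> GanConfig:
        return GanConfig(**{k: getattr(self, k) for k in
                            GanConfig.__dataclass_fields__})

    # -- training -----------------------------------------------------------

    def _init_networks(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.generator_ = UNetGenerator(3, 1, self.generator_base_channels,
                                        self.n_unet_levels, rng)
        self.discriminator_ = PatchGANDiscriminator(
            4, self.discriminator_base_channels, self.n_discriminator_layers, rng)

    def _batch(self, pairs: list[SourceTargetPair], idx) -> tuple[np.ndarray, np.ndarray]:
        x = np.stack([_to_net(pairs[i].source_rgb) for i in idx]).transpose(0, 3, 1, 2)
        y = np.stack([_to_net(pairs[i].target)[None] for i in idx])
        return np.ascontiguousarray(x), np.ascontiguousarray(y)

    def fit(self, pairs: list[SourceTargetPair],
            val_pairs: list[SourceTargetPair] | None = None,
            checkpoint_dir: str | Path | None = None):
        self.config.validate()
        if not pairs:
            raise ValueError("training set is empty")
        for p in pairs:
            if p.target.shape != (self.image_size, self.image_size):
                raise ValueError(
                    f"pair shape {p.target.shape} != image_size {self.image_size}")
        self._init_networks()
        opt_g = Adam(self.generator_.params, self.learning_rate, self.beta1)
        opt_d = Adam(self.discriminator_.params, self.learning_rate, self.beta1)
        shuffle_rng = np.random.default_rng(self.seed + 1)
        self.trace_ = TrainingTrace()

        for epoch in range(1, self.epochs + 1):
            order = shuffle_rng.permutation(len(pairs))
            g_adv_sum = l1_sum = d_sum = 0.0
            n_batches = 0
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                x, y = self._batch(pairs, idx)
                fake = self.generator_(x)

                # --- discriminator: real vs (detached) fake
                opt_d.zero_grad()
                logit_r = self.discriminator_(np.concatenate([x, y], axis=1))
                loss_r, grad_r = bce_with_logits(logit_r, 1.0)
                self.discriminator_.backward(0.5 * grad_r)
                logit_f = self.discriminator_(np.concatenate([x, fake], axis=1))
                loss_f, grad_f = bce_with_logits(logit_f, 0.0)
                self.discriminator_.backward(0.5 * grad_f)
                opt_d.step()

                # --- generator: fool D + L1
                opt_g.zero_grad()
                logit_g = self.discriminator_(np.concatenate([x, fake], axis=1))
                loss_adv, grad_adv = bce_with_logits(logit_g, 1.0)
                dfake = self.discriminator_.backward(grad_adv)[:, 3:]
                loss_l1, grad_l1 = l1_loss(fake, y)
                self.generator_.backward(dfake + self.lambda_l1 * grad_l1)
                opt_g.step()

                if not np.isfinite([loss_r, loss_f, loss_adv, loss_l1]).all():
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: D=({loss_r},{loss_f}) "
                        f"G=({loss_adv},{loss_l1})")
                g_adv_sum += loss_adv
                l1_sum += loss_l1
                d_sum += 0.5 * (loss_r + loss_f)
                n_batches += 1

            self.trace_.epochs.append(epoch)
            self.trace_.loss_g_adv.append(g_adv_sum / n_batches)
            self.trace_.loss_g_l1.append(l1_sum / n_batches)
            self.trace_.loss_d.append(d_sum / n_batches)
            self.trace_.val_residual_tn.append(
                self.validation_residual(val_pairs) if val_pairs else float("nan"))
            if checkpoint_dir is not None:
                self.save_weights(Path(checkpoint_dir) / f"epoch_{epoch:03d}.npz")
        return self

    def validation_residual(self, val_pairs: list[SourceTargetPair]) -> float:
        """Mean absolute generation error in T/N units over held-out pairs."""
        preds = self.predict(np.stack([p.source_rgb for p in val_pairs]))
        targets = np.stack([p.target for p in val_pairs]).astype(float)
        return float(np.mean(np.abs(preds - targets)) / TN_SCALE)

    # -- inference ----------------------------------------------------------

    def predict(self, sources: np.ndarray) -> np.ndarray:
        """Map (N, H, W, 3) 8-bit sources to (N, H, W) continuous 0–255 slices."""
        if not hasattr(self, "generator_"):
            raise RuntimeError("translator is not fitted")
        sources = np.asarray(sources)
        single = sources.ndim == 3
        if single:
            sources = sources[None]
        out = []
        for start in range(0, len(sources), self.batch_size):
            x = _to_net(sources[start:start + self.batch_size]).transpose(0, 3, 1, 2)
            y = self.generator_(np.ascontiguousarray(x))
            out.append(_from_net(y[:, 0]))
        pred = np.concatenate(out, axis=0)
        return pred[0] if single else pred

    # -- persistence --------------------------------------------------------

    def save_weights(self, path: str | Path) -> None:
        arrays = {f"g_{i}": p.value for i, p in enumerate(self.generator_.params)}
        arrays |= {f"d_{i}": p.value for i, p in enumerate(self.discriminator_.params)}
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **arrays)

    def load_weights(self, path: str | Path) -> "Pix2PixTranslator":
        if not hasattr(self, "generator_"):
            self._init_networks()
        with np.load(path) as data:
            for i, p in enumerate(self.generator_.params):
                p.value[...] = data[f"g_{i}"]
            for i, p in enumerate(self.discriminator_.params):
                p.value[...] = data[f"d_{i}"]
        return self


# ---------------------------------------------------------------------------
# functional wrappers

def train(pairs: list[SourceTargetPair], config: GanConfig,
          val_pairs: list[SourceTargetPair] | None = None,
          checkpoint_dir: str | Path | None = None
          ) -> tuple[Pix2PixTranslator, TrainingTrace]:
    model = Pix2PixTranslator.from_config(config).fit(
        pairs, val_pairs=val_pairs, checkpoint_dir=checkpoint_dir)
    return model, model.trace_


def generate_gliomap(model: Pix2PixTranslator, processed: ProcessedSubject,
                     slice_axis: int = 2) -> GliomapVolume:
    """Slice-wise inference re-stacked into a volume on the subject grid.

    Slices are center-cropped/padded to the training image size and the
    predictions embedded back; voxels outside the inference window are zero.
    A generated slice whose dynamic range collapses below
    ``min_dynamic_range`` (8-bit units) is recorded as failed.
    """
    size = model.image_size
    vols = [np.moveaxis(v, slice_axis, 0) for v in
            (processed.t1w_norm, processed.t2w_norm, processed.zce_encoded)]
    n_slices, h, w = vols[0].shape
    sources = np.stack([
        fit_to_square(np.stack([quantize_8bit(v[k]) for v in vols], axis=-1), size)
        for k in range(n_slices)])
    preds = model.predict(sources)
    if not np.isfinite(preds).all():
        raise RuntimeError("non-finite values in generated slices")
    failed = [int(k) for k in range(n_slices)
              if np.ptp(preds[k]) < model.min_dynamic_range]
    encoded = np.stack([embed_from_square(preds[k], (h, w)) for k in range(n_slices)])
    encoded = np.moveaxis(encoded, 0, slice_axis)
    return GliomapVolume(subject_id=processed.subject_id,
                         encoded=np.clip(encoded, 0.0, 255.0), failed_slices=failed)
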