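"""Per-slice source/target pair assembly, augmentation, and cohort splitting.

A training atom is one axial slice: the source is an 8-bit RGB image packing
the three MRI-derived channels (R = normalized T1W, G = normalized T2W,
B = encoded zCE) and the target is the single-channel encoded T/N PET slice.
Pairs are the only place where the continuous 0–255 values are quantized to
8-bit integers (round-half-up), so no stage double-rounds.

Splits are by subject, never by slice, and horizontal-mirroring augmentation
is meant for the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import ModeIntensityNormalizer
from .pet_tn import TumorToNormalScaler
from .zce import ContrastEnhancementZScorer

__all__ = [
    "SourceTargetPair",
    "DatasetSplit",
    "ProcessedSubject",
    "preprocess_subject",
    "build_pairs",
    "mirror_augment",
    "split_cohort",
    "quantize_8bit",
    "export_pairs",
    "load_pairs",
]


def quantize_8bit(values: np.ndarray) -> np.ndarray:
    """Round-half-up quantization of continuous 0–255 values to uint8."""
    return np.floor(np.clip(values, 0.0, 255.0) + 0.5).astype(np.uint8)


@dataclass(frozen=True)
class SourceTargetPair:
    subject_id: str
    slice_index: int
    source_rgb: np.ndarray  # (H, W, 3) uint8; R=T1W, G=T2W, B=zCE
    target: np.ndarray      # (H, W) uint8; encoded T/N
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.source_rgb.shape[:2] != self.target.shape:
            raise ValueError("source and target in-plane shapes differ")
        if self.source_rgb.shape[2] != 3:
            raise ValueError("source must have exactly 3 channels (R=T1, G=T2, B=zCE)")


@dataclass(frozen=True)
class DatasetSplit:
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    seed: int


@dataclass
class ProcessedSubject:
    """A subject after normalization: the GAN-facing continuous volumes."""

    subject_id: str
    t1w_norm: np.ndarray        # 0–255 continuous
    t2w_norm: np.ndarray
    zce_encoded: np.ndarray
    target_encoded: np.ndarray  # encoded T/N, 0–255 continuous
    brain_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    fit_params: dict


def preprocess_subject(subject) -> ProcessedSubject:
    """Full per-subject preprocessing: mode normalization of each MRI
    sequence, zCE construction, and cerebellum-referenced T/N encoding."""
    norms = {}
    for name in ("t1w", "t2w", "t1gd"):
        norms[name] = ModeIntensityNormalizer().fit(
            getattr(subject, name), subject.brain_mask)
    t1w_n = norms["t1w"].transform(subject.t1w)
    t2w_n = norms["t2w"].transform(subject.t2w)
    t1gd_n = norms["t1gd"].transform(subject.t1gd)
    zscorer = ContrastEnhancementZScorer().fit(t1gd_n, t1w_n, subject.brain_mask)
    zce = zscorer.transform(t1gd_n, t1w_n)
    tn_scaler = TumorToNormalScaler().fit(subject.pet_suv, subject.cerebellum_mask)
    tn = tn_scaler.transform(subject.pet_suv)
    return ProcessedSubject(
        subject_id=subject.subject_id,
        t1w_norm=t1w_n, t2w_norm=t2w_n,
        zce_encoded=zce.encoded, target_encoded=tn.encoded,
        brain_mask=subject.brain_mask, voxel_size_mm=subject.voxel_size_mm,
        fit_params={
            "modes": {k: v.mode_ for k, v in norms.items()},
            "zce": {"slope": zscorer.slope_, "intercept": zscorer.intercept_,
                    "residual_sd": zscorer.residual_sd_},
            "cerebellum_mean_suv": tn_scaler.cerebellum_mean_suv_,
        },
    )


def fit_to_square(img: np.ndarray, size: int) -> np.ndarray:
    """Center-crop/pad a 2D (or 2D+channels) image to ``size`` × ``size``."""
    out_shape = (size, size) + img.shape[2:]
    out = np.zeros(out_shape, dtype=img.dtype)
    h, w = img.shape[:2]
    # source window (crop) and destination window (pad), per axis
    sh0 = max((h - size) // 2, 0)
    sw0 = max((w - size) // 2, 0)
    dh0 = max((size - h) // 2, 0)
    dw0 = max((size - w) // 2, 0)
    ch = min(h, size)
    cw = min(w, size)
    out[dh0:dh0 + ch, dw0:dw0 + cw] = img[sh0:sh0 + ch, sw0:sw0 + cw]
    return out


def embed_from_square(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`fit_to_square`: place a square image back on the
    original in-plane grid (zeros where the crop discarded data)."""
    size = img.shape[0]
    h, w = shape
    out = np.zeros((h, w) + img.shape[2:], dtype=img.dtype)
    sh0 = max((h - size) // 2, 0)
    sw0 = max((w - size) // 2, 0)
    dh0 = max((size - h) // 2, 0)
    dw0 = max((size - w) // 2, 0)
    ch = min(h, size)
    cw = min(w, size)
    out[sh0:sh0 + ch, sw0:sw0 + cw] = img[dh0:dh0 + ch, dw0:dw0 + cw]
    return out


def build_pairs(processed: ProcessedSubject, slice_axis: int = 2,
                min_brain_fraction: float = 0.05,
                image_size: int | None = None) -> list[SourceTargetPair]:
    """One pair per slice whose brain-mask coverage is >= ``min_brain_fraction``."""
    vols = [processed.t1w_norm, processed.t2w_norm, processed.zce_encoded,
            processed.target_encoded, processed.brain_mask]
    vols = [np.moveaxis(v, slice_axis, 0) for v in vols]
    t1, t2, zce, tgt, mask = vols
    pairs: list[SourceTargetPair] = []
    for k in range(t1.shape[0]):
        if mask[k].mean() < min_brain_fraction:
            continue
        source = np.stack([quantize_8bit(t1[k]), quantize_8bit(t2[k]),
                           quantize_8bit(zce[k])], axis=-1)
        target = quantize_8bit(tgt[k])
        if image_size is not None:
            source = fit_to_square(source, image_size)
            target = fit_to_square(target, image_size)
        pairs.append(SourceTargetPair(subject_id=processed.subject_id,
                                      slice_index=k, source_rgb=source, target=target))
    if not pairs:
        warnings.warn(f"no slice of {processed.subject_id} meets "
                      f"min_brain_fraction={min_brain_fraction}", stacklevel=2)
    return pairs


def mirror_augment(pairs: list[SourceTargetPair]) -> list[SourceTargetPair]:
    """Double the pair list by horizontal (left-right) mirroring."""
    out = list(pairs)
    for p in pairs:
        out.append(dc_replace(p, source_rgb=p.source_rgb[:, ::-1].copy(),
                              target=p.target[:, ::-1].copy(), mirrored=True))
    return out


def split_cohort(subjects: list[str], n_train: int, seed: int = 0) -> DatasetSplit:
    """Subject-level random split; deterministic under ``seed``."""
    ids = [s if isinstance(s, str) else s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if n_train >= len(ids):
        raise ValueError(f"n_train={n_train} must be < cohort size {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(ids))
    return DatasetSplit(train_subjects=tuple(order[:n_train]),
                        test_subjects=tuple(order[n_train:]), seed=seed)


# ---------------------------------------------------------------------------
# aligned-PNG export: side-by-side [source | target], pix2pix layout

def export_pairs(pairs: list[SourceTargetPair], out_dir: str | Path,
                 partition: str = "train") -> pd.DataFrame:
    import imageio.v3 as iio

    out = Path(out_dir) / partition
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(pairs):
        combined = np.concatenate(
            [p.source_rgb, np.repeat(p.target[..., None], 3, axis=-1)], axis=1)
        fname = f"{p.subject_id}_s{p.slice_index:03d}{'_m' if p.mirrored else ''}.png"
        iio.imwrite(out / fname, combined)
        rows.append({"subject_id": p.subject_id, "slice": p.slice_index,
                     "mirrored": p.mirrored, "file": f"{partition}/{fname}"})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(Path(out_dir) / f"manifest_{partition}.csv", index=False)
    return manifest


def load_pairs(data_dir: str | Path, partition: str = "train") -> list[SourceTargetPair]:
    import imageio.v3 as iio

    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / f"manifest_{partition}.csv")
    pairs = []
    for row in manifest.itertuples():
        combined = iio.imread(data_dir / row.file)
        w = combined.shape[1] // 2
        pairs.append(SourceTargetPair(
            subject_id=row.subject_id, slice_index=int(row.slice),
            source_rgb=combined[:, :w], target=combined[:, w:, 0],
            mirrored=bool(row.mirrored)))
    return pairs
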