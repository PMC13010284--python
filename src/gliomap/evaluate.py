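"""Reconstruction-quality and lesion-level evaluation of generated volumes.

Metrics compare a generated PET-like volume against the ground-truth
tumor-to-normal (T/N) volume:

* voxel-wise residual error in T/N units (absolute mean ± SD, plus the signed
  mean which exposes any systematic over/underestimation of uptake);
* peak SNR ``10·log10(255² / MSE)``, a "regular" SNR defined here as the
  reference-energy ratio ``10·log10(Σ truth² / Σ (truth − pred)²)``, and the
  structural similarity index (Gaussian 11×11 window, σ = 1.5, K1 = 0.01,
  K2 = 0.03, dynamic range 255) averaged over axial slices;
* a Sørensen-Dice curve over T/N thresholds between the lesions the two
  volumes predict;
* volume-expansion ratios |enhancing ∪ lesion(t)| / |enhancing| quantifying
  how much a T/N-thresholded lesion extends the gadolinium-enhancing target;
* cubic voxel-of-interest statistics at tissue-sampling coordinates and the
  OLS regression of VOI-mean T/N on tumor cell density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from .pet_tn import TN_SCALE, TNVolume
from .gan import GliomapVolume

__all__ = [
    "EvaluationReport", "residual_error", "image_quality", "dice_coefficient",
    "dice_vs_threshold", "volume_expansion", "expansion_vs_threshold",
    "voi_statistics", "density_regression", "evaluate_subject",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(1.1, 2.01, 0.1), 2))


def _tn_of(vol) -> np.ndarray:
    if isinstance(vol, GliomapVolume):
        return vol.tn
    if isinstance(vol, TNVolume):
        return vol.tn_values
    return np.asarray(vol, dtype=float)


def residual_error(gliomap, truth, mask: np.ndarray) -> tuple[float, float, float]:
    """(mean, SD, signed mean) of the voxel-wise T/N difference over ``mask``."""
    a, b = _tn_of(gliomap), _tn_of(truth)
    if a.shape != b.shape:
        raise ValueError("volume grids differ")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("evaluation mask is empty")
    diff = (a - b)[mask]
    return float(np.mean(np.abs(diff))), float(np.std(np.abs(diff))), float(np.mean(diff))


def _encoded_of(vol) -> np.ndarray:
    if isinstance(vol, (GliomapVolume, TNVolume)):
        return vol.encoded
    return np.asarray(vol, dtype=float)


def image_quality(gliomap, truth, slice_axis: int = 2
                  ) -> tuple[float, float, float]:
    """(peak SNR dB, regular SNR dB, SSIM) on the 0–255 encoded volumes."""
    a = _encoded_of(gliomap).astype(float)
    b = _encoded_of(truth).astype(float)
    if a.shape != b.shape:
        raise ValueError("volume grids differ")
    err = np.mean((a - b) ** 2)
    if err == 0:
        psnr = snr = float("inf")
    else:
        psnr = 10.0 * np.log10(255.0**2 / err)
        denom = np.sum((a - b) ** 2)
        snr = 10.0 * np.log10(np.sum(b**2) / denom) if denom > 0 else float("inf")
    a2 = np.moveaxis(a, slice_axis, 0)
    b2 = np.moveaxis(b, slice_axis, 0)
    ssim_vals = [
        structural_similarity(b2[k], a2[k], data_range=255.0,
                              gaussian_weights=True, sigma=1.5,
                              use_sample_covariance=False)
        for k in range(a2.shape[0])
    ]
    return float(psnr), float(snr), float(np.mean(ssim_vals))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both sets are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_vs_threshold(gliomap, truth, thresholds=DEFAULT_THRESHOLDS
                      ) -> list[tuple[float, float]]:
    """Dice between the lesions the two volumes predict, per T/N threshold."""
    a, b = _tn_of(gliomap), _tn_of(truth)
    curve = []
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be positive")
        curve.append((float(t), dice_coefficient(a >= t, b >= t)))
    return curve


def volume_expansion(lesion: np.ndarray, enhancing_mask: np.ndarray,
                     union: bool = True) -> float:
    """|enhancing ∪ lesion| / |enhancing| (or plain |lesion|/|enhancing|)."""
    lesion = np.asarray(lesion, dtype=bool)
    enh = np.asarray(enhancing_mask, dtype=bool)
    n_enh = int(enh.sum())
    if n_enh == 0:
        raise ValueError("enhancing mask is empty")
    n = int((enh | lesion).sum()) if union else int(lesion.sum())
    return n / n_enh


def expansion_vs_threshold(volume, enhancing_mask: np.ndarray,
                           thresholds=DEFAULT_THRESHOLDS) -> list[tuple[float, float]]:
    tn = _tn_of(volume)
    return [(float(t), volume_expansion(tn >= t, enhancing_mask)) for t in thresholds]


def voi_statistics(volume, position_mm, voxel_size_mm,
                   voi_edge_mm: float = 10.0) -> tuple[float, float]:
    """Mean and SD of decoded T/N within a cubic VOI centered at a physical
    coordinate (origin at the grid center, matching the phantom convention)."""
    tn = _tn_of(volume)
    lo_idx, hi_idx = [], []
    for ax in range(3):
        n, dv = tn.shape[ax], voxel_size_mm[ax]
        center_vox = position_mm[ax] / dv + (n - 1) / 2.0
        half = voi_edge_mm / (2.0 * dv)
        lo = int(np.ceil(center_vox - half))
        hi = int(np.floor(center_vox + half)) + 1
        if lo < 0 or hi > n:
            raise ValueError(f"VOI exits the grid on axis {ax}")
        lo_idx.append(lo)
        hi_idx.append(hi)
    voi = tn[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
    return float(voi.mean()), float(voi.std())


def density_regression(samples: list[tuple[float, float]]
                       ) -> tuple[float, float, float, float]:
    """OLS of VOI-mean T/N on cell density: (slope, intercept, p, r).

    ``samples`` are (voi_mean_tn, cell_density) tuples; the two-sided p-value
    for the slope comes from the t distribution with n-2 degrees of freedom.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    tn = np.array([s[0] for s in samples], dtype=float)
    density = np.array([s[1] for s in samples], dtype=float)
    if np.ptp(density) == 0:
        raise ValueError("constant density; regression undefined")
    res = stats.linregress(density, tn)
    return float(res.slope), float(res.intercept), float(res.pvalue), float(res.rvalue)


@dataclass
class EvaluationReport:
    subject_id: str
    residual_mean_tn: float
    residual_sd_tn: float
    residual_signed_mean_tn: float
    psnr_db: float
    snr_db: float
    ssim: float
    dice_curve: list[tuple[float, float]]
    expansion_curve_gliomap: list[tuple[float, float]]
    expansion_curve_truth: list[tuple[float, float]]
    n_failed_slices: int = 0
    voi_samples: list[dict] = field(default_factory=list)
    density_fit: dict | None = None

    def dice_at(self, threshold: float) -> float:
        for t, d in self.dice_curve:
            if abs(t - threshold) < 1e-9:
                return d
        raise KeyError(f"threshold {threshold} not in curve")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))

    def curves_to_csv(self, path: str | Path) -> None:
        rows = [{"threshold": t, "dice": d, "expansion_gliomap": eg, "expansion_truth": et}
                for (t, d), (_, eg), (_, et)
                in zip(self.dice_curve, self.expansion_curve_gliomap,
                       self.expansion_curve_truth)]
        pd.DataFrame(rows).to_csv(path, index=False)


def evaluate_subject(gliomap: GliomapVolume, truth, subject,
                     thresholds=DEFAULT_THRESHOLDS) -> EvaluationReport:
    """Full per-subject battery against the ground-truth T/N volume."""
    mean, sd, signed = residual_error(gliomap, truth, subject.brain_mask)
    psnr, snr, ssim = image_quality(gliomap, truth)
    voi_samples = []
    for p in subject.sampling_points:
        try:
            m, s = voi_statistics(gliomap, p.position_mm, subject.voxel_size_mm)
        except ValueError:
            continue
        voi_samples.append({"position_mm": list(p.position_mm), "voi_mean_tn": m,
                            "voi_sd_tn": s, "true_density": p.true_density})
    return EvaluationReport(
        subject_id=gliomap.subject_id,
        residual_mean_tn=mean, residual_sd_tn=sd, residual_signed_mean_tn=signed,
        psnr_db=psnr, snr_db=snr, ssim=ssim,
        dice_curve=dice_vs_threshold(gliomap, truth, thresholds),
        expansion_curve_gliomap=expansion_vs_threshold(gliomap, subject.enhancing_mask,
                                                       thresholds),
        expansion_curve_truth=expansion_vs_threshold(truth, subject.enhancing_mask,
                                                     thresholds),
        n_failed_slices=len(gliomap.failed_slices),
        voi_samples=voi_samples,
    )
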