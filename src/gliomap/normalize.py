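"""Mode-anchored 8-bit MRI intensity normalization.

Each MRI volume is rescaled so that the mode of its 256-bin brain-masked
intensity histogram maps to 75 on a 0–255 scale:

    SI_normalized = SI_original * 75 / mode(SI_256bins)

with values above 255 ceilinged to 255.  Anchoring the histogram mode — in
practice the dominant normal-brain tissue intensity — to a fixed point of the
8-bit range removes arbitrary per-scanner global intensity gain without
observing any other subject, which makes the procedure usable prospectively,
one subject at a time.

The scaling is applied to the full (non-skull-stripped) volume; only the mode
is computed inside the brain mask.  Values are kept continuous on the 0–255
scale here; quantization to 8-bit integers happens once, at dataset export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MODE_ANCHOR",
    "NormalizedVolume",
    "ModeIntensityNormalizer",
    "brain_histogram_mode",
    "normalize_intensity",
]

MODE_ANCHOR = 75.0
EIGHT_BIT_MAX = 255.0


@dataclass
class NormalizedVolume:
    """A volume on the continuous 0–255 scale plus the mode that produced it."""

    values: np.ndarray
    mode_value: float
    source_modality: str = ""

    def __post_init__(self) -> None:
        if self.mode_value <= 0:
            raise ValueError("mode_value must be positive")


def brain_histogram_mode(volume: np.ndarray, brain_mask: np.ndarray,
                         n_bins: int = 256) -> float:
    """Center of the most populated of ``n_bins`` equal-width bins over
    brain-mask voxel intensities.  Ties resolve to the lowest-intensity bin.
    """
    volume = np.asarray(volume, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if volume.shape != brain_mask.shape:
        raise ValueError("volume and brain_mask shapes differ")
    vals = volume[brain_mask]
    if vals.size == 0:
        raise ValueError("brain mask is empty; cannot compute histogram mode")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        mode = lo  # constant volume: the histogram is a single spike
    else:
        counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
        k = int(np.argmax(counts))  # argmax returns the first (lowest) tied bin
        mode = float(0.5 * (edges[k] + edges[k + 1]))
    if mode <= 0:
        raise ValueError(f"histogram mode {mode} is non-positive; cannot normalize")
    return mode


def normalize_intensity(volume: np.ndarray, mode_value: float,
                        source_modality: str = "") -> NormalizedVolume:
    """Map each voxel v to clip(v * 75 / mode, 0, 255)."""
    if mode_value <= 0:
        raise ValueError("mode_value must be positive")
    # divide first so a voxel exactly at the mode maps to exactly 75.0
    out = np.asarray(volume, dtype=float) / mode_value * MODE_ANCHOR
    out = np.clip(out, 0.0, EIGHT_BIT_MAX)
    return NormalizedVolume(values=out, mode_value=float(mode_value),
                            source_modality=source_modality)


class ModeIntensityNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer for the mode-anchored normalization.

    ``fit(volume, brain_mask)`` computes the brain-histogram mode;
    ``transform(volume)`` applies the fixed scaling to any volume on the
    same intensity scale (usually the one it was fitted on).

    Attributes
    ----------
    mode_ : float
        The 256-bin brain-histogram mode found at fit time.
    """

    def __init__(self, n_bins: int = 256, anchor: float = MODE_ANCHOR):
        self.n_bins = n_bins
        self.anchor = anchor

    def fit(self, volume: np.ndarray, brain_mask: np.ndarray):
        self.mode_ = brain_histogram_mode(volume, brain_mask, n_bins=self.n_bins)
        return self

    def transform(self, volume: np.ndarray) -> np.ndarray:
        if not hasattr(self, "mode_"):
            raise RuntimeError("normalizer is not fitted")
        return np.clip(np.asarray(volume, dtype=float) / self.mode_ * self.anchor,
                       0.0, EIGHT_BIT_MAX)

    def fit_transform(self, volume: np.ndarray, brain_mask: np.ndarray = None,
                      **fit_params) -> np.ndarray:
        return self.fit(volume, brain_mask).transform(volume)
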