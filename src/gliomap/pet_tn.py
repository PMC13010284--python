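"""Tumor-to-normal (T/N) PET normalization against a cerebellar reference.

Methionine-PET SUV values carry injected-dose and scanner scale; dividing by
the mean SUV of the cerebellum (a normal reference region) converts the volume
to a dimensionless tumor-to-normal ratio comparable across subjects.  The T/N
volume is encoded to 8 bits as clip(T/N · 51, 0, 255), so the usable ratio
range [0, 5] fills the 8-bit scale and T/N ≥ 5 saturates at 255; the exact
inverse on that range is pixel / 51.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["TN_SCALE", "TNVolume", "TumorToNormalScaler", "tn_normalize", "tn_decode"]

TN_SCALE = 51.0


@dataclass
class TNVolume:
    tn_values: np.ndarray
    cerebellum_mean_suv: float
    encoded: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.cerebellum_mean_suv <= 0:
            raise ValueError("cerebellum mean SUV must be positive")
        if self.encoded is None:
            self.encoded = np.clip(self.tn_values * TN_SCALE, 0.0, 255.0)


def tn_normalize(pet_suv: np.ndarray, cerebellum_mask: np.ndarray) -> TNVolume:
    """Divide the SUV volume by the mean SUV inside the cerebellum mask."""
    pet_suv = np.asarray(pet_suv, dtype=float)
    mask = np.asarray(cerebellum_mask, dtype=bool)
    if pet_suv.shape != mask.shape:
        raise ValueError("pet volume and cerebellum mask shapes differ")
    if not mask.any():
        raise ValueError("cerebellum mask is empty")
    ref = float(pet_suv[mask].mean())
    if ref <= 0:
        raise ValueError(f"cerebellum mean SUV {ref} is non-positive")
    return TNVolume(tn_values=pet_suv / ref, cerebellum_mean_suv=ref)


def tn_decode(encoded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert the ×51 encoding: returns (T/N volume, saturated-voxel mask).

    Voxels at exactly 255 are flagged saturated — their true ratio is only
    known to be ≥ 5.
    """
    encoded = np.asarray(encoded, dtype=float)
    if encoded.min() < 0 or encoded.max() > 255:
        raise ValueError("encoded values must lie in [0, 255]")
    return encoded / TN_SCALE, encoded >= 255.0


class TumorToNormalScaler(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer for cerebellum-referenced T/N scaling.

    Attributes
    ----------
    cerebellum_mean_suv_ : float
        Reference mean SUV found at fit time.
    """

    def fit(self, pet_suv: np.ndarray, cerebellum_mask: np.ndarray):
        self.cerebellum_mean_suv_ = tn_normalize(pet_suv, cerebellum_mask).cerebellum_mean_suv
        return self

    def transform(self, pet_suv: np.ndarray) -> TNVolume:
        if not hasattr(self, "cerebellum_mean_suv_"):
            raise RuntimeError("scaler is not fitted")
        return TNVolume(tn_values=np.asarray(pet_suv, dtype=float) / self.cerebellum_mean_suv_,
                        cerebellum_mean_suv=self.cerebellum_mean_suv_)

    def inverse_transform(self, encoded: np.ndarray) -> np.ndarray:
        return tn_decode(encoded)[0]

    def fit_transform(self, pet_suv, cerebellum_mask=None, **fit_params) -> TNVolume:
        return self.fit(pet_suv, cerebellum_mask).transform(pet_suv)
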