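"""z-score contrast-enhancement (zCE) mapping.

Gadolinium enhancement is the part of the normalized T1Gd signal that the
normalized T1W signal does not predict.  Per subject, an ordinary
least-squares line T1Gd ≈ a·T1W + b is fitted over brain-mask voxels; the
voxel-wise residual divided by the global residual SD is that voxel's
enhancement z-score.  The z map highlights even slight enhancement that is
hard to see on raw T1Gd, and is encoded to 8 bits as clip(z·51, 0, 255)
(z = 5 saturates at 255; negative z, i.e. hypo-enhancement, clips to 0 —
a deliberately lossy encoding since the 8-bit image carries no sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .normalize import NormalizedVolume

__all__ = ["ZCEVolume", "ContrastEnhancementZScorer", "fit_t1gd_on_t1w", "zce_map"]

Z_SCALE = 51.0


@dataclass
class ZCEVolume:
    z_values: np.ndarray
    regression_slope: float
    regression_intercept: float
    residual_sd: float
    encoded: np.ndarray  # clip(z * 51, 0, 255), continuous


def _as_array(v) -> np.ndarray:
    return v.values if isinstance(v, NormalizedVolume) else np.asarray(v, dtype=float)


def fit_t1gd_on_t1w(t1gd_norm, t1w_norm, brain_mask: np.ndarray
                    ) -> tuple[float, float, float]:
    """OLS of normalized T1Gd on normalized T1W over brain-mask voxels.

    Returns (slope, intercept, residual_sd) where residual_sd is the
    population SD of the fit residuals over the same voxels.
    """
    y = _as_array(t1gd_norm)[np.asarray(brain_mask, dtype=bool)]
    x = _as_array(t1w_norm)[np.asarray(brain_mask, dtype=bool)]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("T1W is constant inside the brain mask; regression undefined")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * x + intercept)
    residual_sd = float(np.std(resid))
    # a residual SD at rounding-noise level on the 0-255 scale is a perfect fit
    if residual_sd < 1e-8:
        raise ValueError("zero residual SD (perfect fit); z-scores undefined")
    return float(slope), float(intercept), residual_sd


def zce_map(t1gd_norm, t1w_norm, fit: tuple[float, float, float]) -> ZCEVolume:
    """z-score each voxel of the full grid against the fitted line and encode."""
    slope, intercept, residual_sd = fit
    if residual_sd <= 0:
        raise ValueError("residual_sd must be positive")
    z = (_as_array(t1gd_norm) - slope * _as_array(t1w_norm) - intercept) / residual_sd
    encoded = np.clip(z * Z_SCALE, 0.0, 255.0)
    return ZCEVolume(z_values=z, regression_slope=slope,
                     regression_intercept=intercept, residual_sd=residual_sd,
                     encoded=encoded)


class ContrastEnhancementZScorer(TransformerMixin, BaseEstimator):
    """Sklearn-style estimator for the zCE construction.

    ``fit(t1gd_norm, t1w_norm, brain_mask)`` estimates the per-subject null
    line; ``transform(t1gd_norm, t1w_norm)`` produces the encoded zCE volume.

    Attributes
    ----------
    slope_, intercept_ : float
        The fitted T1Gd-on-T1W line.
    residual_sd_ : float
        Population SD of the brain-mask fit residuals (the z-score unit).
    """

    def fit(self, t1gd_norm, t1w_norm, brain_mask: np.ndarray):
        self.slope_, self.intercept_, self.residual_sd_ = fit_t1gd_on_t1w(
            t1gd_norm, t1w_norm, brain_mask)
        return self

    def transform(self, t1gd_norm, t1w_norm) -> ZCEVolume:
        if not hasattr(self, "residual_sd_"):
            raise RuntimeError("z-scorer is not fitted")
        return zce_map(t1gd_norm, t1w_norm,
                       (self.slope_, self.intercept_, self.residual_sd_))

    def fit_transform(self, t1gd_norm, t1w_norm, brain_mask=None, **fit_params):
        return self.fit(t1gd_norm, t1w_norm, brain_mask).transform(t1gd_norm, t1w_norm)
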