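"""NDVI computation and cross-sensor consistency measurement.

NDVI = (NIR − Red) / (NIR + Red) from surface reflectance.  Cross-sensor
consistency is measured the way inter-calibration studies do: mean NDVI
over small homogeneous windows (default 3×3) in each sensor's image, an
ordinary least-squares line of sensor B on sensor A through those window
means, and the coefficient of determination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConsistencyResult",
    "compute_ndvi",
    "extract_window_means",
    "fit_sensor_consistency",
]


@dataclass(frozen=True)
class ConsistencyResult:
    """OLS fit of one sensor's window-mean NDVI on another's."""

    slope: float
    intercept: float
    r_squared: float
    n_windows: int

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")
        if self.n_windows < 3:
            raise ValueError("need at least 3 windows")


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Per-pixel NDVI from red and NIR surface reflectance.

    Pixels with ``red + nir == 0`` (or non-finite inputs) are flagged NaN
    and propagate through downstream fits.  Raises if every pixel is
    flagged.
    """
    red = np.asarray(red, float)
    nir = np.asarray(nir, float)
    denom = red + nir
    valid = np.isfinite(denom) & (denom != 0)
    if not np.any(valid):
        raise ValueError("NDVI undefined everywhere (red + nir == 0)")
    out = np.full(np.broadcast(red, nir).shape, np.nan)
    out[valid] = (nir[valid] - red[valid]) / denom[valid]
    return out


def extract_window_means(image: np.ndarray, centers, window: int = 3) -> np.ndarray:
    """Mean NDVI over odd-sized square windows centred on ``centers``.

    Every window must lie fully inside the raster; NaNs inside a window
    are excluded from its mean.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if window < 1 or window % 2 == 0:
        raise ValueError("window size must be odd and positive")
    half = window // 2
    means = np.empty(len(centers))
    for i, (r, c) in enumerate(centers):
        if r - half < 0 or c - half < 0 or r + half >= image.shape[0] or c + half >= image.shape[1]:
            raise IndexError(f"window at center ({r}, {c}) extends outside the raster")
        means[i] = np.nanmean(image[r - half:r + half + 1, c - half:c + half + 1])
    return means


def fit_sensor_consistency(x: np.ndarray, y: np.ndarray) -> ConsistencyResult:
    """OLS line of sensor-B window means on sensor-A window means.

    Returns slope, intercept and R²; NaN pairs are dropped before the
    fit.  Requires at least 3 finite pairs and non-constant ``x``.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired window means")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x is constant")
    res = stats.linregress(x, y)
    return ConsistencyResult(slope=float(res.slope), intercept=float(res.intercept),
                             r_squared=float(res.rvalue ** 2), n_windows=int(x.size))
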