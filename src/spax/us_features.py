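"""First-order B-mode ultrasound features: echointensity and heterogeneity.

Fibrotic liver remodeling raises tissue echogenicity (mean gray level) and
texture heterogeneity.  Heterogeneity is quantified as the mean over ROI
pixels of the local gray-level variance in a small square neighborhood
(clipped at image borders and restricted to ROI pixels); a global-variance
mode over the whole ROI is available for sensitivity analysis.  All
variances are population (divisor n) variances.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["echointensity", "heterogeneity"]


def _check_roi(image: np.ndarray, roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError(f"ROI shape {roi.shape} != image shape {image.shape}")
    if not roi.any():
        raise ValueError("ROI is empty")
    return roi


def echointensity(bmode: np.ndarray, roi: np.ndarray) -> float:
    """Mean gray level over the ROI."""
    bmode = np.asarray(bmode, dtype=float)
    roi = _check_roi(bmode, roi)
    return float(bmode[roi].mean())


def _local_variance_map(
    img: np.ndarray, mask: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Masked local population variance per pixel; second output marks
    pixels whose neighborhood contains at least one mask pixel."""
    m = mask.astype(float)
    size = (window, window)
    n = uniform_filter(m, size=size, mode="constant")
    s1 = uniform_filter(img * m, size=size, mode="constant")
    s2 = uniform_filter(img * img * m, size=size, mode="constant")
    valid = n > 1e-12
    n_safe = np.where(valid, n, 1.0)
    var = s2 / n_safe - (s1 / n_safe) ** 2
    return np.clip(var, 0.0, None), valid


def heterogeneity(
    bmode: np.ndarray, roi: np.ndarray, mode: str = "local", window_px: int = 5
) -> float:
    """Gray-level heterogeneity over the ROI.

    mode "local" (default): mean over ROI pixels of the variance within a
    ``window_px`` × ``window_px`` neighborhood restricted to the ROI.
    mode "global": population variance of all ROI gray levels.
    """
    bmode = np.asarray(bmode, dtype=float)
    roi = _check_roi(bmode, roi)
    if mode == "global":
        return float(bmode[roi].var())
    if mode != "local":
        raise ValueError(f"unknown heterogeneity mode {mode!r}")
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    var, _valid = _local_variance_map(bmode, roi, window_px)
    return float(var[roi].mean())
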