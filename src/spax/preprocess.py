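"""Skinline segmentation, ROI handling, and fluence correction.

Spectral coloring — the depth- and wavelength-dependent distortion of
measured photoacoustic spectra caused by optical attenuation in overlying
tissue — is the main obstacle to quantitative unmixing.  The decoloring
step divides each voxel by the modeled fluence
Φ(λ, z) = Φ0 · exp(-μ_eff(λ) · d_mm), where depth d_mm is measured from the
per-column skinline (the tissue/background watershed found on the B-mode
image), not from the transducer face.  The correction gain is capped so
uncorrectable deep voxels cannot dominate the unmixing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu

from .phantom import MultispectralStack
from .spectra import Spectrum, resample_spectrum

__all__ = [
    "Skinline",
    "segment_skinline",
    "correct_fluence",
    "rect_roi",
    "load_roi_mask",
    "save_roi_mask",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class Skinline:
    """Per-lateral-column depth index (px) of the first tissue row."""

    depths: np.ndarray
    no_tissue: np.ndarray  # columns where no tissue was found (depth = image depth)

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=int)
        nt = np.asarray(self.no_tissue, dtype=bool)
        if d.ndim != 1 or nt.shape != d.shape:
            raise ValueError("depths and no_tissue must be 1-D of equal length")
        if np.any(d < 0):
            raise ValueError("skinline depths must be non-negative")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "no_tissue", nt)

    @classmethod
    def flat(cls, depth_px: int, n_cols: int) -> "Skinline":
        return cls(np.full(n_cols, depth_px), np.zeros(n_cols, dtype=bool))


def segment_skinline(bmode: np.ndarray, smooth_px: int = 5) -> Skinline:
    """First supra-threshold row per column, median-smoothed across columns.

    The global threshold is Otsu's; columns with no supra-threshold pixel are
    assigned the image depth (no tissue) and flagged.
    """
    img = np.asarray(bmode, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("bmode must be a non-empty 2-D image")
    h, w = img.shape
    if img.max() == img.min():
        log.warning("constant B-mode image: no skinline found in any column")
        return Skinline(np.full(w, h), np.ones(w, dtype=bool))
    thr = threshold_otsu(img)
    above = img > thr
    has = above.any(axis=0)
    first = np.where(has, above.argmax(axis=0), h)
    if (~has).any():
        log.warning("%d columns contain no supra-threshold pixel", int((~has).sum()))
    if smooth_px >= 2:
        first = median_filter(first.astype(float), size=smooth_px, mode="nearest")
        first = np.rint(first).astype(int)
    return Skinline(np.clip(first, 0, h), ~has)


def correct_fluence(
    stack: MultispectralStack,
    skin: Skinline,
    mu_eff: Spectrum,
    surface_fluence: float = 1.0,
    max_gain: float = 50.0,
) -> MultispectralStack:
    """Divide each sub-skin voxel by Φ(λ, z); voxels above the skinline are
    untouched.  The per-voxel gain exp(μ·d)/Φ0 is capped at ``max_gain``."""
    if surface_fluence <= 0:
        raise ValueError("surface_fluence must be positive")
    if max_gain <= 0:
        raise ValueError("max_gain must be positive")
    if mu_eff.grid != stack.grid:
        mu_eff = resample_spectrum(mu_eff, stack.grid)
    h, w = stack.spatial_shape
    if skin.depths.shape != (w,):
        raise ValueError("skinline must have one depth per lateral column")
    depth_mm = (np.arange(h)[:, None] - skin.depths[None, :]) * stack.pixel_size_mm
    below = depth_mm >= 0
    depth_mm = np.where(below, depth_mm, 0.0)
    gain = np.exp(mu_eff.values[:, None, None] * depth_mm[None, :, :]) / surface_fluence
    capped = gain > max_gain
    n_capped = int(capped[:, below].sum())
    if n_capped:
        log.info("fluence gain capped at %gx for %d voxel-wavelengths", max_gain, n_capped)
    gain = np.minimum(gain, max_gain)
    gain[:, ~below] = 1.0
    return MultispectralStack(
        data=stack.data * gain,
        grid=stack.grid,
        bmode=stack.bmode,
        roi_mask=stack.roi_mask,
        pixel_size_mm=stack.pixel_size_mm,
    )


def rect_roi(r0: int, c0: int, r1: int, c1: int, shape: tuple[int, int]) -> np.ndarray:
    """Rectangular ROI over half-open ranges [r0, r1) × [c0, c1); row 0 is
    the shallowest row."""
    h, w = shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"rectangle [{r0}:{r1}, {c0}:{c1}] does not fit in {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def load_roi_mask(path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a 0/255 mask image; nonzero pixels are inside the ROI."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    mask = img > 127
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"ROI mask shape {mask.shape} != expected {tuple(shape)}")
    if not mask.any():
        raise ValueError(f"ROI mask {path} is empty")
    return mask


def save_roi_mask(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
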