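"""Synthetic phantom generator with retained ground truth.

Emulates the study data: a multispectral photoacoustic stack (one frame per
wavelength, 680–970 nm @ 5 nm) co-registered with a speckled B-mode
ultrasound image, over a liver-like scene of chromophore concentration maps.

Forward model per sub-skin pixel (z, x) and wavelength λ::

    p(λ, z, x) = Γ · Φ0 · exp(-μ_eff(λ) · d_mm(z, x)) · Σ_k c_k(z, x) ε_k(λ) + N(0, σ)

where Γ is a Grüneisen-like photoacoustic efficiency, Φ0 the surface
fluence, μ_eff(λ) the effective optical attenuation (1/mm), d_mm the depth
below the per-column skinline, c_k the chromophore concentration maps and
ε_k the library absorption spectra.  The fluence model is a 1-D depth
exponential per wavelength — an analytic stand-in with a pluggable μ_eff
spectrum; the pixels above the skinline carry no tissue signal.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` streams, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .spectra import SpectraLibrary, Spectrum, WavelengthGrid, acquisition_grid

__all__ = [
    "PhantomSpec",
    "MultispectralStack",
    "PhantomTruth",
    "default_mu_eff",
    "simulate_stack",
    "simulate_bmode",
    "simulate_progression",
    "fibrosis_phantom",
    "so2_phantom",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class MultispectralStack:
    """A (n_wavelengths, depth, lateral) PA stack with its B-mode companion."""

    data: np.ndarray
    grid: WavelengthGrid
    bmode: np.ndarray
    roi_mask: np.ndarray
    pixel_size_mm: float = 0.1

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[0] != len(self.grid):
            raise ValueError(
                f"stack shape {data.shape} inconsistent with grid of {len(self.grid)}"
            )
        bmode = np.asarray(self.bmode, dtype=float)
        roi = np.asarray(self.roi_mask, dtype=bool)
        if bmode.shape != data.shape[1:] or roi.shape != data.shape[1:]:
            raise ValueError("bmode/roi shape must match the spatial frame shape")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "bmode", bmode)
        object.__setattr__(self, "roi_mask", roi)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def pixel_spectrum(self, row: int, col: int, name: str = "") -> Spectrum:
        return Spectrum(self.grid, self.data[:, row, col], name or f"pixel({row},{col})")


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description for the forward model (see module docstring)."""

    shape: tuple[int, int]
    concentrations: Mapping[str, np.ndarray]
    pixel_size_mm: float = 0.1
    grueneisen_gamma: float = 1.0
    surface_fluence: float = 1.0
    mu_eff: Spectrum | None = None  # None → default_mu_eff(lib)
    noise_sd: float = 0.0
    skin_depth_px: int | np.ndarray = 0
    roi_mask: np.ndarray | None = None
    bmode_mean: float = 103.4
    bmode_local_variance: float = 135.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.surface_fluence <= 0:
            raise ValueError("surface_fluence must be positive")
        if not self.concentrations:
            raise ValueError("need at least one chromophore concentration map")
        for name, cmap in self.concentrations.items():
            cmap = np.asarray(cmap)
            if cmap.shape != tuple(self.shape):
                raise ValueError(f"concentration map '{name}' shape {cmap.shape} != {self.shape}")
            if np.any(cmap < 0):
                raise ValueError(f"concentration map '{name}' has negative values")
        if self.mu_eff is not None and np.any(self.mu_eff.values < 0):
            raise ValueError("mu_eff must be non-negative")

    def skinline_array(self) -> np.ndarray:
        """Per-column first tissue row."""
        sk = np.asarray(self.skin_depth_px)
        if sk.ndim == 0:
            sk = np.full(self.shape[1], int(sk))
        if sk.shape != (self.shape[1],):
            raise ValueError("skin_depth_px must be scalar or one value per column")
        return sk.astype(int)

    def default_roi(self) -> np.ndarray:
        """All sub-skin pixels unless an explicit ROI was given."""
        if self.roi_mask is not None:
            return np.asarray(self.roi_mask, dtype=bool)
        rows = np.arange(self.shape[0])[:, None]
        return rows >= self.skinline_array()[None, :]


@dataclass(frozen=True, eq=False)
class PhantomTruth:
    """Ground truth retained for recovery tests."""

    spec: PhantomSpec
    noiseless: np.ndarray
    so2: np.ndarray  # NaN where total hemoglobin is zero


def default_mu_eff(
    lib: SpectraLibrary,
    *,
    baseline: float = 0.03,
    blood_weight: float = 0.10,
    water_weight: float = 0.08,
) -> Spectrum:
    """Effective attenuation (1/mm) as baseline + blood + water absorption.

    The blood and water terms make the fluence spectrally non-flat, so
    spectral coloring genuinely distorts deep spectra and decoloring is a
    meaningful correction.  Magnitudes give μ_eff ≈ 0.03–0.2 /mm, typical of
    soft tissue in the NIR-I window.
    """
    blood = 0.5 * lib["hbo2"].values + 0.5 * lib["hb"].values
    vals = baseline + blood_weight * blood + water_weight * lib["water"].values
    return Spectrum(lib.grid, vals, "mu_eff")


def _forward_noiseless(spec: PhantomSpec, lib: SpectraLibrary) -> np.ndarray:
    missing = set(spec.concentrations) - set(lib.names)
    if missing:
        raise KeyError(f"chromophores {sorted(missing)} missing from the library")
    grid = lib.grid
    mu = spec.mu_eff if spec.mu_eff is not None else default_mu_eff(lib)
    if mu.grid != grid:
        raise ValueError("mu_eff must be sampled on the library grid")
    h, w = spec.shape
    skin = spec.skinline_array()
    depth_mm = (np.arange(h)[:, None] - skin[None, :]) * spec.pixel_size_mm
    below = depth_mm >= 0
    depth_mm = np.where(below, depth_mm, 0.0)

    absorbed = np.zeros((len(grid), h, w))
    for name, cmap in spec.concentrations.items():
        absorbed += lib[name].values[:, None, None] * np.asarray(cmap, dtype=float)
    fluence = spec.surface_fluence * np.exp(-mu.values[:, None, None] * depth_mm[None, :, :])
    out = spec.grueneisen_gamma * fluence * absorbed
    out[:, ~below] = 0.0
    return out


def simulate_stack(
    spec: PhantomSpec, lib: SpectraLibrary
) -> tuple[MultispectralStack, PhantomTruth]:
    """Run the forward model; returns the noisy stack and its ground truth."""
    noiseless = _forward_noiseless(spec, lib)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5AC]))
    data = noiseless.copy()
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    bmode = simulate_bmode(
        spec, spec.bmode_mean, spec.bmode_local_variance, seed=spec.seed
    )
    hbo2 = np.asarray(spec.concentrations.get("hbo2", np.zeros(spec.shape)), dtype=float)
    hb = np.asarray(spec.concentrations.get("hb", np.zeros(spec.shape)), dtype=float)
    thb = hbo2 + hb
    with np.errstate(invalid="ignore", divide="ignore"):
        so2 = np.where(thb > 0, hbo2 / np.where(thb > 0, thb, 1.0), np.nan)

    stack = MultispectralStack(
        data=data,
        grid=lib.grid,
        bmode=bmode,
        roi_mask=spec.default_roi(),
        pixel_size_mm=spec.pixel_size_mm,
    )
    return stack, PhantomTruth(spec=spec, noiseless=noiseless, so2=so2)


def _masked_local_variance(img: np.ndarray, mask: np.ndarray, window: int) -> float:
    # population variance in a window×window neighborhood, ROI-restricted
    from .us_features import _local_variance_map

    var, valid = _local_variance_map(img, mask, window)
    return float(var[valid & mask].mean())


def simulate_bmode(
    spec: PhantomSpec,
    target_mean: float,
    target_local_variance: float,
    seed: int | None = None,
    *,
    speckle_looks: float = 4.0,
    window_px: int = 5,
) -> np.ndarray:
    """Speckled B-mode companion image, calibrated to first-order targets.

    Multiplicative gamma speckle (``speckle_looks`` looks) is scaled and
    offset so that the ROI mean matches ``target_mean`` and the mean local
    gray-level variance matches ``target_local_variance``; then clipped to
    the 8-bit display range.  Pixels above the skinline are background (0).
    """
    if not 0.0 <= target_mean <= 255.0:
        raise ValueError("target_mean must be within [0, 255]")
    if target_local_variance < 0:
        raise ValueError("target_local_variance must be non-negative")
    h, w = spec.shape
    roi = spec.default_roi()
    above = np.arange(h)[:, None] < spec.skinline_array()[None, :]

    if target_local_variance == 0:
        img = np.full((h, w), float(target_mean))
        img[above] = 0.0
        return img

    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed if seed is None else seed), 0xB30DE])
    )
    g = rng.gamma(speckle_looks, 1.0 / speckle_looks, size=(h, w))
    lv = _masked_local_variance(g, roi, window_px)
    a = np.sqrt(target_local_variance / lv) if lv > 0 else 0.0
    img = target_mean + a * (g - 1.0)
    img = np.clip(img, 0.0, 255.0)
    measured = float(img[roi].mean())
    if target_mean > 0 and abs(measured - target_mean) > 0.05 * target_mean:
        log.warning(
            "B-mode targets infeasible after clipping: ROI mean %.1f vs target %.1f",
            measured,
            target_mean,
        )
    img[above] = 0.0
    return img


def simulate_progression(
    base_spec: PhantomSpec,
    collagen_scales: Sequence[float],
    lib: SpectraLibrary,
    seed: int | None = None,
) -> list[tuple[MultispectralStack, PhantomTruth]]:
    """Longitudinal series: timepoint t scales the collagen map by
    ``collagen_scales[t]``; everything else is identical except the noise
    realization (fresh per-timepoint seed derived from ``seed``)."""
    if len(collagen_scales) == 0:
        raise ValueError("need at least one collagen scale")
    if np.any(np.asarray(collagen_scales) <= 0):
        raise ValueError("collagen scales must be positive")
    if "collagen3" not in base_spec.concentrations:
        raise KeyError("base phantom has no 'collagen3' concentration map")
    root = int(base_spec.seed if seed is None else seed)
    out = []
    for t, scale in enumerate(collagen_scales):
        conc = dict(base_spec.concentrations)
        conc["collagen3"] = np.asarray(conc["collagen3"], dtype=float) * float(scale)
        spec_t = replace(base_spec, concentrations=conc, seed=root * 1000 + t)
        out.append(simulate_stack(spec_t, lib))
    return out


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma_px: float
) -> np.ndarray:
    """Unit-mean, positive smooth random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma_px)
    f = f / max(f.std(), 1e-12)
    return np.clip(1.0 + 0.35 * f, 0.05, None)


def fibrosis_phantom(
    shape: tuple[int, int] = (128, 256),
    *,
    seed: int = 0,
    noise_frac_of_peak: float = 0.02,
    collagen_amplitude: float = 2.0,
    n_blobs: int = 5,
    blob_sigma_px: tuple[float, float] = (6.0, 14.0),
    skin_depth_px: int = 8,
    so2_range: tuple[float, float] = (0.55, 0.85),
    lib: SpectraLibrary | None = None,
    bmode_mean: float = 103.4,
    bmode_local_variance: float = 135.0,
    pixel_size_mm: float = 0.1,
) -> PhantomSpec:
    """Liver-like three-chromophore phantom (collagen3, HbO2, Hb).

    Parenchyma is a smooth total-hemoglobin field split by a smooth SO2
    field; fibrosis is modeled as ``n_blobs`` focal Gaussian collagen
    deposits below the skinline.  ``noise_frac_of_peak`` sets the additive
    noise sd as a fraction of the noiseless peak signal.
    """
    if lib is None:
        from .library import reference_library

        lib = reference_library()
    h, w = shape
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1B]))

    thb = _smooth_field(rng, shape, sigma_px=max(h, w) / 16)
    lo, hi = so2_range
    s = gaussian_filter(rng.standard_normal(shape), max(h, w) / 10)
    s = (s - s.min()) / max(s.max() - s.min(), 1e-12)
    so2 = lo + (hi - lo) * s

    collagen = np.zeros(shape)
    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        r0 = rng.uniform(skin_depth_px + 8, h - 8)
        c0 = rng.uniform(8, w - 8)
        sig = rng.uniform(*blob_sigma_px)
        amp = collagen_amplitude * rng.uniform(0.6, 1.0)
        collagen += amp * np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sig**2)))

    sub_skin = np.zeros(shape, dtype=bool)
    sub_skin[skin_depth_px:, :] = True
    margin = max(2, w // 32)
    roi = np.zeros(shape, dtype=bool)
    roi[skin_depth_px + 2 : h - 2, margin : w - margin] = True

    conc = {
        "collagen3": collagen * sub_skin,
        "hbo2": thb * so2 * sub_skin,
        "hb": thb * (1.0 - so2) * sub_skin,
    }
    spec = PhantomSpec(
        shape=shape,
        concentrations=conc,
        pixel_size_mm=pixel_size_mm,
        skin_depth_px=skin_depth_px,
        roi_mask=roi,
        seed=seed,
        bmode_mean=bmode_mean,
        bmode_local_variance=bmode_local_variance,
    )
    if noise_frac_of_peak > 0:
        peak = float(_forward_noiseless(spec, lib).max())
        spec = replace(spec, noise_sd=noise_frac_of_peak * peak)
    return spec


def so2_phantom(
    shape: tuple[int, int] = (64, 128),
    *,
    seed: int = 0,
    noise_frac_of_peak: float = 0.02,
    lib: SpectraLibrary | None = None,
) -> PhantomSpec:
    """Two-chromophore (HbO2/Hb) phantom with a smoothly varying SO2 map,
    for oxygen-saturation recovery tests."""
    if lib is None:
        from .library import reference_library

        lib = reference_library()
    h, w = shape
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x502]))
    thb = _smooth_field(rng, shape, sigma_px=max(h, w) / 12)
    # lateral SO2 ramp plus smooth perturbation spans most of [0, 1]
    ramp = np.linspace(0.15, 0.95, w)[None, :] * np.ones((h, 1))
    pert = gaussian_filter(rng.standard_normal(shape), max(h, w) / 10)
    so2 = np.clip(ramp + 0.08 * pert / max(pert.std(), 1e-12), 0.02, 0.98)
    conc = {"hbo2": thb * so2, "hb": thb * (1.0 - so2)}
    spec = PhantomSpec(shape=shape, concentrations=conc, skin_depth_px=0, seed=seed)
    if noise_frac_of_peak > 0:
        peak = float(_forward_noiseless(spec, lib).max())
        spec = replace(spec, noise_sd=noise_frac_of_peak * peak)
    return spec
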