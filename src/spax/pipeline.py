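"""End-to-end orchestration: stack → decoloring → blind unmixing → metrics.

``unmix_stack`` runs the full blind analysis of one multispectral stack;
``analyze_timepoint`` additionally derives the per-timepoint fibrosis
metrics (collagen correlation, percent area, SO2 summary, ratio, B-mode
features) used to build longitudinal tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import reference_library
from .phantom import MultispectralStack, default_mu_eff
from .preprocess import Skinline, correct_fluence, segment_skinline
from .quantify import (
    TimepointMetrics,
    collagen_correlation,
    collagen_so2_ratio,
    compute_so2,
    percent_area,
    roi_mean_spectrum,
    so2_percent,
)
from .spectra import COLLAGEN_BAND_NM, SpectraLibrary, Spectrum
from .unmix import (
    UnmixingResult,
    assign_components,
    nnmf_unmix,
    project_abundances,
    superpixel_subsample,
    svd_denoise,
)
from .us_features import echointensity, heterogeneity

__all__ = ["unmix_stack", "analyze_timepoint", "analyze_progression", "reference_so2"]


def unmix_stack(
    stack: MultispectralStack,
    roi: np.ndarray | None = None,
    lib: SpectraLibrary | None = None,
    *,
    skinline: Skinline | None = None,
    mu_eff: Spectrum | None = None,
    surface_fluence: float = 1.0,
    fluence_correction: bool = True,
    max_gain: float = 50.0,
    n_superpixels: int = 200,
    compactness: float = 10.0,
    energy_frac: float = 0.99,
    n_components: int | None = None,
    band: tuple[float, float] = COLLAGEN_BAND_NM,
    seed: int = 0,
    nnmf_max_iter: int = 500,
    nnmf_tol: float = 1e-7,
) -> UnmixingResult:
    """Blind unmixing of one stack.

    Stages: skinline segmentation (from the B-mode image unless given),
    fluence correction with ``mu_eff`` (library-derived default), SLIC
    superpixel subsampling over the ROI, SVD denoising with automatic rank
    selection at ``energy_frac``, NNMF with that rank (or an explicit
    ``n_components``), full-resolution NNLS abundance projection, and
    greedy assignment of endmembers to library chromophores.
    """
    lib = lib if lib is not None else reference_library()
    roi = stack.roi_mask if roi is None else np.asarray(roi, dtype=bool)
    if fluence_correction:
        if skinline is None:
            skinline = segment_skinline(stack.bmode)
        if mu_eff is None:
            mu_eff = default_mu_eff(lib)
        work = correct_fluence(stack, skinline, mu_eff, surface_fluence, max_gain)
    else:
        work = stack

    sp = superpixel_subsample(work, roi, n_superpixels, compactness)
    X_low, rank, svals = svd_denoise(sp.mean_spectra, energy_frac)
    k = rank if n_components is None else int(n_components)
    k = max(1, min(k, min(X_low.shape)))
    S, _A_sub, info = nnmf_unmix(X_low, k, seed=seed, max_iter=nnmf_max_iter, tol=nnmf_tol)
    A_full = project_abundances(work, roi, S)
    assignment = assign_components(S, work.grid, lib, band)
    return UnmixingResult(
        S=S,
        A=A_full,
        rank=rank,
        singular_values=svals,
        assignment=assignment,
        grid=work.grid,
        error_trace=info["error_trace"],
        reconstruction_error=info["reconstruction_error"],
        clipped_negatives=info["clipped_negatives"],
    )


def reference_so2(
    stack: MultispectralStack,
    roi: np.ndarray | None = None,
    lib: SpectraLibrary | None = None,
) -> np.ma.MaskedArray:
    """SO2 from NNLS of each pixel spectrum onto the library HbO2/Hb spectra
    (supervised oximetry; no blind-unmixing rotation ambiguity)."""
    lib = lib if lib is not None else reference_library()
    roi = stack.roi_mask if roi is None else np.asarray(roi, dtype=bool)
    S = np.stack([lib["hbo2"].values, lib["hb"].values])
    A = project_abundances(stack, roi, S)
    so2 = compute_so2(A[0], A[1])
    return np.ma.masked_array(so2, mask=np.ma.getmaskarray(so2) | ~roi)


def analyze_timepoint(
    stack: MultispectralStack,
    label: str,
    roi: np.ndarray | None = None,
    lib: SpectraLibrary | None = None,
    *,
    animal: str | None = None,
    correlation_mode: str = "roi_mean",
    so2_source: str = "reference",
    so2_mode: str = "mean",
    threshold_mode: str | float = "otsu",
    result: UnmixingResult | None = None,
    **unmix_kwargs,
) -> TimepointMetrics:
    """Compute all per-timepoint fibrosis metrics for one stack.

    ``correlation_mode``: "roi_mean" correlates the ROI-mean corrected
    spectrum with the collagen reference (the per-animal entry point);
    "endmember" correlates the collagen-assigned endmember instead.
    ``so2_source``: "reference" (supervised NNLS oximetry, default) or
    "unmixed" (blind HbO2/Hb components, requires both assigned).
    """
    lib = lib if lib is not None else reference_library()
    roi = stack.roi_mask if roi is None else np.asarray(roi, dtype=bool)
    if result is None:
        result = unmix_stack(stack, roi, lib, **unmix_kwargs)

    # metrics are computed on the decolored stack the unmixer saw
    if unmix_kwargs.get("fluence_correction", True):
        skinline = unmix_kwargs.get("skinline") or segment_skinline(stack.bmode)
        mu = unmix_kwargs.get("mu_eff") or default_mu_eff(lib)
        work = correct_fluence(
            stack,
            skinline,
            mu,
            unmix_kwargs.get("surface_fluence", 1.0),
            unmix_kwargs.get("max_gain", 50.0),
        )
    else:
        work = stack

    if correlation_mode == "roi_mean":
        corr = collagen_correlation(roi_mean_spectrum(work, roi), lib)
    elif correlation_mode == "endmember":
        k = result.component_for("collagen3")
        if k is None:
            raise ValueError("no endmember was assigned to collagen3")
        corr = result.assignment[k][1]
    else:
        raise ValueError(f"unknown correlation_mode {correlation_mode!r}")

    area = percent_area(result.abundance_for("collagen3"), roi, threshold_mode)

    if so2_source == "reference":
        so2 = reference_so2(work, roi, lib)
    elif so2_source == "unmixed":
        so2 = compute_so2(result.abundance_for("hbo2"), result.abundance_for("hb"))
        so2 = np.ma.masked_array(so2, mask=np.ma.getmaskarray(so2) | ~roi)
    else:
        raise ValueError(f"unknown so2_source {so2_source!r}")
    so2_pct = so2_percent(so2, roi, mode=so2_mode)

    return TimepointMetrics(
        label=label,
        animal=animal,
        collagen_ref_correlation=corr,
        collagen_percent_area=area,
        so2_percent=so2_pct,
        collagen_to_so2_ratio=collagen_so2_ratio(area, so2_pct),
        echogenicity=echointensity(stack.bmode, roi),
        heterogeneity=heterogeneity(stack.bmode, roi),
    )


def analyze_progression(
    series: list[tuple[MultispectralStack, str]],
    roi: np.ndarray | None = None,
    lib: SpectraLibrary | None = None,
    *,
    animal: str | None = None,
    shared_threshold: bool = True,
    return_results: bool = False,
    **kwargs,
) -> list[TimepointMetrics] | tuple[list[TimepointMetrics], list[UnmixingResult]]:
    """Metrics for one animal's longitudinal series of (stack, label).

    With ``shared_threshold`` (default) the collagen percent-area threshold
    is a single Otsu threshold over the pooled collagen abundance values of
    all timepoints, so areas are comparable across visits: a per-timepoint
    threshold adapts to each map's own scale and would hide longitudinal
    growth in collagen signal.
    """
    if not series:
        raise ValueError("series is empty")
    lib = lib if lib is not None else reference_library()
    grid0 = series[0][0].grid
    if any(stk.grid != grid0 for stk, _ in series):
        raise ValueError("all timepoints must share one wavelength grid")
    unmix_keys = {
        "skinline", "mu_eff", "surface_fluence", "fluence_correction", "max_gain",
        "n_superpixels", "compactness", "energy_frac", "n_components", "band",
        "seed", "nnmf_max_iter", "nnmf_tol",
    }
    unmix_kwargs = {k: v for k, v in kwargs.items() if k in unmix_keys}
    results = [
        unmix_stack(stk, roi if roi is not None else stk.roi_mask, lib, **unmix_kwargs)
        for stk, _ in series
    ]
    threshold_mode: str | float = kwargs.get("threshold_mode", "otsu")
    if shared_threshold:
        from skimage.filters import threshold_otsu

        pooled = np.concatenate(
            [
                r.abundance_for("collagen3")[roi if roi is not None else stk.roi_mask]
                for (stk, _), r in zip(series, results)
            ]
        )
        if pooled.max() > pooled.min():
            threshold_mode = float(threshold_otsu(pooled))
    metric_kwargs = {
        k: v for k, v in kwargs.items() if k not in unmix_keys and k != "threshold_mode"
    }
    metrics = [
        analyze_timepoint(
            stk,
            label,
            roi,
            lib,
            animal=animal,
            threshold_mode=threshold_mode,
            result=r,
            **metric_kwargs,
            **unmix_kwargs,
        )
        for (stk, label), r in zip(series, results)
    ]
    return (metrics, results) if return_results else metrics
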