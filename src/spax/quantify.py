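"""Downstream fibrosis metrics.

Per timepoint the study tracks: the Pearson correlation of the liver
spectrum with the collagen III reference (on the 880–970 nm detection
band), the percent area of the ROI with supra-threshold collagen abundance,
a tissue oxygen-saturation (SO2) summary, the collagen-area / SO2 ratio,
and the first-order B-mode features.  This module computes those metrics
and assembles the longitudinal mean ± sd table across animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .phantom import MultispectralStack
from .spectra import (
    COLLAGEN_BAND_NM,
    SpectraLibrary,
    Spectrum,
    band_restrict,
    pearson_similarity,
)

__all__ = [
    "TimepointMetrics",
    "roi_mean_spectrum",
    "collagen_correlation",
    "percent_area",
    "compute_so2",
    "so2_percent",
    "collagen_so2_ratio",
    "longitudinal_table",
]

_METRIC_FIELDS = (
    "collagen_ref_correlation",
    "collagen_percent_area",
    "so2_percent",
    "collagen_to_so2_ratio",
    "echogenicity",
    "heterogeneity",
)


@dataclass(frozen=True)
class TimepointMetrics:
    """All per-timepoint metrics for one animal (one stack)."""

    label: str
    collagen_ref_correlation: float
    collagen_percent_area: float
    so2_percent: float
    collagen_to_so2_ratio: float
    echogenicity: float
    heterogeneity: float
    animal: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.collagen_ref_correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        for name in ("collagen_percent_area", "so2_percent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.collagen_to_so2_ratio < 0:
            raise ValueError("collagen/SO2 ratio must be non-negative")


def roi_mean_spectrum(stack: MultispectralStack, roi: np.ndarray | None = None) -> Spectrum:
    """Per-wavelength mean over the ROI pixels."""
    roi = stack.roi_mask if roi is None else np.asarray(roi, dtype=bool)
    if roi.shape != stack.spatial_shape:
        raise ValueError("ROI shape does not match the stack")
    if not roi.any():
        raise ValueError("ROI is empty")
    return Spectrum(stack.grid, stack.data[:, roi].mean(axis=1), "roi_mean")


def collagen_correlation(
    spectrum_or_stack: Spectrum | MultispectralStack,
    lib: SpectraLibrary,
    band: tuple[float, float] = COLLAGEN_BAND_NM,
    roi: np.ndarray | None = None,
) -> float:
    """Pearson correlation with the collagen III reference on ``band``.

    Accepts either a spectrum directly (ROI-mean spectrum or a
    collagen-assigned endmember) or a stack, in which case its ROI-mean
    spectrum is used.
    """
    if isinstance(spectrum_or_stack, MultispectralStack):
        s = roi_mean_spectrum(spectrum_or_stack, roi)
    else:
        s = spectrum_or_stack
    ref = lib["collagen3"]
    if s.grid != lib.grid:
        from .spectra import resample_spectrum

        s = resample_spectrum(s, lib.grid)
    return pearson_similarity(band_restrict(s, *band), band_restrict(ref, *band))


def percent_area(
    abundance_map: np.ndarray,
    roi: np.ndarray,
    threshold_mode: str | float = "otsu",
    frac: float = 0.5,
) -> float:
    """Percent of ROI pixels whose abundance exceeds a threshold.

    ``threshold_mode``: "otsu" (default, Otsu on the ROI abundance
    histogram), "fixed_frac" (τ = frac · map max over ROI), or a number used
    directly as an absolute threshold.
    """
    roi = np.asarray(roi, dtype=bool)
    amap = np.asarray(abundance_map, dtype=float)
    if amap.shape != roi.shape:
        raise ValueError("abundance map and ROI shapes differ")
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = amap[roi]
    if isinstance(threshold_mode, (int, float)):
        tau = float(threshold_mode)
    elif threshold_mode == "otsu":
        if vals.max() == vals.min():
            return 0.0
        tau = float(threshold_otsu(vals))
    elif threshold_mode == "fixed_frac":
        tau = frac * float(vals.max())
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return 100.0 * float((vals > tau).sum()) / vals.size


def compute_so2(A_hbo2: np.ndarray, A_hb: np.ndarray, eps: float = 1e-12) -> np.ma.MaskedArray:
    """SO2 = HbO2 / (HbO2 + Hb); pixels with no hemoglobin are masked out
    (excluded from summaries, not set to 0)."""
    A_hbo2 = np.asarray(A_hbo2, dtype=float)
    A_hb = np.asarray(A_hb, dtype=float)
    if A_hbo2.shape != A_hb.shape:
        raise ValueError("HbO2 and Hb maps must have the same shape")
    if np.any(A_hbo2 < 0) or np.any(A_hb < 0):
        raise ValueError("abundance maps must be non-negative")
    total = A_hbo2 + A_hb
    invalid = total <= eps
    so2 = np.where(invalid, 0.0, A_hbo2 / np.where(invalid, 1.0, total))
    return np.ma.masked_array(so2, mask=invalid)


def so2_percent(
    so2: np.ma.MaskedArray,
    roi: np.ndarray | None = None,
    mode: str = "mean",
    area_threshold: float = 0.5,
) -> float:
    """Summarize an SO2 map as a percentage.

    mode "mean" (default): 100 · mean SO2 over valid ROI pixels.
    mode "area": percent of valid ROI pixels with SO2 > ``area_threshold``.
    """
    so2 = np.ma.asarray(so2)
    sel = np.ones(so2.shape, dtype=bool) if roi is None else np.asarray(roi, dtype=bool)
    valid = sel & ~np.ma.getmaskarray(so2)
    if not valid.any():
        raise ValueError("no valid SO2 pixels in the ROI")
    vals = np.asarray(so2)[valid]
    if mode == "mean":
        return 100.0 * float(vals.mean())
    if mode == "area":
        return 100.0 * float((vals > area_threshold).sum()) / vals.size
    raise ValueError(f"unknown SO2 summary mode {mode!r}")


def collagen_so2_ratio(collagen_percent_area: float, so2_pct: float) -> float:
    """Collagen burden per unit of tissue oxygen saturation."""
    if so2_pct <= 0:
        raise ValueError("so2_percent must be positive")
    if collagen_percent_area < 0:
        raise ValueError("collagen percent area must be non-negative")
    return collagen_percent_area / so2_pct


def longitudinal_table(
    metrics: Sequence[TimepointMetrics],
    label_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per timepoint label: n and mean ± sd (sample sd, ddof=1; NaN
    for a single animal) of every metric across animals sharing the label.

    Rows follow ``label_order`` when given, else sorted label order — so the
    table is invariant to the input ordering.
    """
    if not metrics:
        raise ValueError("need at least one timepoint")
    df = pd.DataFrame(
        [{f.name: getattr(m, f.name) for f in fields(TimepointMetrics)} for m in metrics]
    )
    if label_order is not None:
        missing = set(df["label"]) - set(label_order)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in label_order")
        order = [l for l in label_order if l in set(df["label"])]
    else:
        order = sorted(df["label"].unique())
    rows = []
    for label in order:
        g = df[df["label"] == label]
        row: dict[str, object] = {"label": label, "n": len(g)}
        for name in _METRIC_FIELDS:
            row[f"{name}_mean"] = float(g[name].mean())
            row[f"{name}_sd"] = float(g[name].std(ddof=1)) if len(g) > 1 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
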