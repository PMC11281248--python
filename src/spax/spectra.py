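"""Wavelength grids, chromophore spectra, and spectral similarity.

Spectral photoacoustic imaging (sPAI) acquires one image per optical
wavelength; every downstream step (fluence correction, unmixing, component
identification) reasons about per-pixel absorption spectra sampled on a
common wavelength grid.  This module holds the spectral data model: the
grid, single spectra, libraries of reference chromophore spectra
(collagen III, oxy-/deoxy-hemoglobin, water, fat), CSV I/O, and Pearson
similarity used to match unmixed components to known chromophores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NIR_MIN_NM",
    "NIR_MAX_NM",
    "WavelengthGrid",
    "Spectrum",
    "SpectraLibrary",
    "resample_spectrum",
    "band_restrict",
    "pearson_similarity",
    "load_spectra_csv",
    "save_spectra_csv",
]

# Acquisition window of the NIR-I sPAI protocol this package models.
NIR_MIN_NM = 680.0
NIR_MAX_NM = 970.0


@dataclass(frozen=True, eq=False)
class WavelengthGrid:
    """Strictly increasing wavelengths (nm) within the 680–970 nm window."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(vals)):
            raise ValueError("wavelength grid contains non-finite values")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if vals[0] < NIR_MIN_NM or vals[-1] > NIR_MAX_NM:
            raise ValueError(
                f"wavelengths must lie within [{NIR_MIN_NM:g}, {NIR_MAX_NM:g}] nm, "
                f"got range [{vals[0]:g}, {vals[-1]:g}]"
            )
        object.__setattr__(self, "values", vals)
        self.values.setflags(write=False)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        """Uniform grid ``start, start+step, ..., stop`` (inclusive)."""
        if step <= 0:
            raise ValueError("step must be positive")
        n = int(round((stop - start) / step)) + 1
        vals = start + step * np.arange(n)
        if abs(vals[-1] - stop) > 1e-9:
            raise ValueError(f"({start}, {stop}) is not an integer number of {step} nm steps")
        return cls(vals)

    def __len__(self) -> int:
        return int(self.values.size)

    def __iter__(self) -> Iterator[float]:
        return iter(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=0.0, atol=1e-9)
        )

    def __hash__(self) -> int:  # frozen dataclass with eq=False would use id()
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    def __repr__(self) -> str:
        return (
            f"WavelengthGrid({self.values[0]:g}..{self.values[-1]:g} nm, "
            f"n={len(self)})"
        )


# Canonical acquisition grid: 680–970 nm in 5 nm steps (59 samples).
def acquisition_grid() -> WavelengthGrid:
    return WavelengthGrid.from_range(NIR_MIN_NM, NIR_MAX_NM, 5.0)


# Collagen is resolved on the long-wavelength end of the window, where its
# ~930 nm absorption peak sits and blood absorption is comparatively flat.
COLLAGEN_BAND_NM: tuple[float, float] = (880.0, 970.0)


@dataclass(frozen=True, eq=False)
class Spectrum:
    """Absorption values (arbitrary units) on a wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.grid),):
            raise ValueError(
                f"spectrum '{self.name}' has {vals.size} values for a grid of "
                f"{len(self.grid)} wavelengths"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"spectrum '{self.name}' contains non-finite values")
        object.__setattr__(self, "values", vals)
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return len(self.grid)

    def with_name(self, name: str) -> "Spectrum":
        return Spectrum(self.grid, self.values, name)


def resample_spectrum(s: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate ``s`` onto ``target``; extrapolation is refused."""
    lo, hi = s.grid.values[0], s.grid.values[-1]
    tol = 1e-9
    bad = target.values[(target.values < lo - tol) | (target.values > hi + tol)]
    if bad.size:
        raise ValueError(
            f"cannot resample '{s.name}': wavelength {bad[0]:g} nm is outside "
            f"the source range [{lo:g}, {hi:g}] nm"
        )
    vals = np.interp(target.values, s.grid.values, s.values)
    return Spectrum(target, vals, s.name)


def band_restrict(s: Spectrum, lo_nm: float, hi_nm: float) -> Spectrum:
    """Keep samples with ``lo_nm <= λ <= hi_nm`` (closed interval)."""
    if lo_nm > hi_nm:
        raise ValueError(f"band limits reversed: [{lo_nm:g}, {hi_nm:g}]")
    keep = (s.grid.values >= lo_nm - 1e-9) & (s.grid.values <= hi_nm + 1e-9)
    if not keep.any():
        raise ValueError(
            f"band [{lo_nm:g}, {hi_nm:g}] nm contains no samples of the grid "
            f"{s.grid!r}"
        )
    return Spectrum(WavelengthGrid(s.grid.values[keep]), s.values[keep], s.name)


def pearson_similarity(a: Spectrum, b: Spectrum) -> float:
    """Pearson correlation between two spectra on a common grid.

    A constant spectrum has no shape to correlate; that is an error, not a
    correlation of zero.
    """
    if a.grid != b.grid:
        raise ValueError("spectra are on different grids; resample first")
    if len(a) < 2:
        raise ValueError("need at least two wavelengths for a correlation")
    av = a.values - a.values.mean()
    bv = b.values - b.values.mean()
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0.0 or nb == 0.0:
        offender = a.name if na == 0.0 else b.name
        raise ValueError(f"spectrum '{offender}' has zero variance")
    return float(np.clip(av @ bv / (na * nb), -1.0, 1.0))


class SpectraLibrary(Mapping[str, Spectrum]):
    """Named spectra resampled onto one common grid at insertion."""

    def __init__(self, spectra: Iterable[Spectrum] | Mapping[str, Spectrum]):
        if isinstance(spectra, Mapping):
            items = [s.with_name(k) for k, s in spectra.items()]
        else:
            items = list(spectra)
        if not items:
            raise ValueError("library needs at least one spectrum")
        names = [s.name for s in items]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromophore names: {sorted(names)}")
        if any(not s.name for s in items):
            raise ValueError("every library spectrum needs a name")
        self._grid = items[0].grid
        self._spectra: dict[str, Spectrum] = {
            s.name: (s if s.grid == self._grid else resample_spectrum(s, self._grid))
            for s in items
        }

    @property
    def grid(self) -> WavelengthGrid:
        return self._grid

    @property
    def names(self) -> list[str]:
        return list(self._spectra)

    def __getitem__(self, name: str) -> Spectrum:
        return self._spectra[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._spectra)

    def __len__(self) -> int:
        return len(self._spectra)

    def matrix(self) -> np.ndarray:
        """(n_chromophores, n_wavelengths) stacked in insertion order."""
        return np.stack([s.values for s in self._spectra.values()])

    def resampled(self, target: WavelengthGrid) -> "SpectraLibrary":
        return SpectraLibrary([resample_spectrum(s, target) for s in self._spectra.values()])

    def __repr__(self) -> str:
        return f"SpectraLibrary({self.names}, grid={self._grid!r})"


def load_spectra_csv(path: str | Path) -> SpectraLibrary:
    """Read a library from CSV with a ``wavelength_nm`` column plus one
    column per chromophore."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{path}: missing required 'wavelength_nm' column")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path}: wavelengths must be strictly increasing (no duplicates)")
    grid = WavelengthGrid(wl)
    names = [c for c in df.columns if c != "wavelength_nm"]
    if not names:
        raise ValueError(f"{path}: no chromophore columns")
    return SpectraLibrary(
        [Spectrum(grid, df[c].to_numpy(dtype=float), c) for c in names]
    )


def save_spectra_csv(lib: SpectraLibrary, path: str | Path) -> None:
    df = pd.DataFrame({"wavelength_nm": lib.grid.values})
    for name in lib.names:
        df[name] = lib[name].values
    df.to_csv(path, index=False, float_format="%.12g")
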