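"""Bundled reference chromophore library.

The unmixing stage identifies blind endmembers by correlating them with
reference absorption spectra of the chromophores expected in liver tissue:
collagen III, oxyhemoglobin (HbO2), deoxyhemoglobin (Hb), water, and fat.
The package ships a fixture library of literature-shaped spectra on the
680–970 nm @ 5 nm acquisition grid, normalized to unit maximum:

* collagen III — broad NIR peak centered at 930 nm (the band exploited for
  collagen detection);
* HbO2 — shallow minimum near 690 nm, rising smoothly toward 970 nm;
* Hb — characteristic 760 nm peak, decaying at longer wavelengths;
* water — nearly transparent below 900 nm, steep rise toward its 975 nm band;
* fat (lipid) — narrow 925 nm peak with a weak 760 nm overtone.

Relative amplitudes between chromophores are absorbed into the simulated
concentrations, so unit-max shapes are sufficient for shape-based
identification; no molar-extinction units are implied.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .spectra import SpectraLibrary, Spectrum, acquisition_grid, load_spectra_csv

__all__ = [
    "REFERENCE_CHROMOPHORES",
    "build_reference_library",
    "reference_library",
]

REFERENCE_CHROMOPHORES = ("collagen3", "hbo2", "hb", "water", "fat")


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def build_reference_library() -> SpectraLibrary:
    """Construct the reference shapes analytically (source of the fixture CSV)."""
    grid = acquisition_grid()
    wl = grid.values

    collagen3 = 0.06 + 0.94 * _gauss(wl, 930.0, 38.0)
    hbo2 = 0.18 + 0.82 / (1.0 + np.exp(-(wl - 815.0) / 55.0)) - 0.06 * _gauss(wl, 690.0, 25.0)
    hb = 0.22 + 0.78 * _gauss(wl, 758.0, 48.0) + 0.10 * _gauss(wl, 905.0, 60.0)
    water = 0.015 + 0.985 * _gauss(wl, 975.0, 42.0)
    fat = 0.05 + 0.90 * _gauss(wl, 925.0, 16.0) + 0.12 * _gauss(wl, 760.0, 28.0)

    spectra = []
    for name, vals in [
        ("collagen3", collagen3),
        ("hbo2", hbo2),
        ("hb", hb),
        ("water", water),
        ("fat", fat),
    ]:
        vals = np.clip(vals, 0.0, None)
        spectra.append(Spectrum(grid, vals / vals.max(), name))
    return SpectraLibrary(spectra)


def reference_library() -> SpectraLibrary:
    """Load the packaged reference-spectra CSV fixture."""
    path = resources.files("spax").joinpath("data/reference_spectra.csv")
    with resources.as_file(path) as p:
        lib = load_spectra_csv(p)
    missing = set(REFERENCE_CHROMOPHORES) - set(lib.names)
    if missing:
        raise RuntimeError(f"packaged reference library is missing {sorted(missing)}")
    return lib
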