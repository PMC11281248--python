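"""Blind spectral unmixing: SVD denoise, superpixel subsampling, NNMF,
abundance projection, and component identification.

The pipeline factorizes the (pixels × wavelengths) spectral matrix X into
non-negative endmember spectra S and abundances A, X ≈ A·S.  To keep the
factorization well-conditioned and fast, it is fit on superpixel mean
spectra (SLIC clusters over the ROI) after an SVD low-rank truncation whose
rank — the number of singular values needed to reach a set energy fraction
— doubles as the automatic choice for the number of NNMF components.
Abundances at full resolution are then obtained per pixel by non-negative
least squares against the fitted endmembers, and each endmember is
identified by greedy one-to-one Pearson matching against the reference
chromophore library (collagen on its 880–970 nm detection band, other
chromophores on the full acquisition band).

The NNMF itself uses deterministic NNDSVDa initialization and multiplicative
Frobenius updates with a logged reconstruction-error trace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from skimage.segmentation import slic

from .phantom import MultispectralStack
from .spectra import (
    COLLAGEN_BAND_NM,
    SpectraLibrary,
    Spectrum,
    WavelengthGrid,
    band_restrict,
    pearson_similarity,
)

__all__ = [
    "PixelSpectraMatrix",
    "SuperpixelMap",
    "UnmixingResult",
    "svd_denoise",
    "superpixel_subsample",
    "nnmf_unmix",
    "project_abundances",
    "assign_components",
]

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True, eq=False)
class PixelSpectraMatrix:
    """(n_samples × n_wavelengths) spectra with sample provenance."""

    X: np.ndarray
    grid: WavelengthGrid
    provenance: np.ndarray | None = None  # pixel coords or superpixel ids

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.grid):
            raise ValueError(f"matrix shape {X.shape} inconsistent with grid of {len(self.grid)}")
        if np.isnan(X).any():
            raise ValueError("spectral matrix contains NaN")
        object.__setattr__(self, "X", X)


@dataclass(frozen=True, eq=False)
class SuperpixelMap:
    """SLIC labels over the ROI (−1 outside) with per-superpixel mean spectra."""

    labels: np.ndarray
    n_superpixels: int
    mean_spectra: np.ndarray  # (n_superpixels, n_wavelengths)
    grid: WavelengthGrid
    sizes: np.ndarray

    def spectra_matrix(self) -> PixelSpectraMatrix:
        return PixelSpectraMatrix(
            self.mean_spectra, self.grid, provenance=np.arange(self.n_superpixels)
        )


@dataclass(frozen=True, eq=False)
class UnmixingResult:
    """Endmembers S (unit-max rows), full-resolution abundance maps A, and
    the component → chromophore assignment."""

    S: np.ndarray  # (K, n_wavelengths)
    A: np.ndarray  # (K, depth, lateral), zeros outside the ROI
    rank: int
    singular_values: np.ndarray
    assignment: dict[int, tuple[str, float]]
    grid: WavelengthGrid
    error_trace: np.ndarray
    reconstruction_error: float
    clipped_negatives: int = 0

    @property
    def n_components(self) -> int:
        return self.S.shape[0]

    def endmember(self, k: int) -> Spectrum:
        name = self.assignment.get(k, ("unknown", math.nan))[0]
        return Spectrum(self.grid, self.S[k], f"endmember{k}:{name}")

    def component_for(self, chromophore: str) -> int | None:
        for k, (name, _corr) in self.assignment.items():
            if name == chromophore:
                return k
        return None

    def abundance_for(self, chromophore: str) -> np.ndarray:
        k = self.component_for(chromophore)
        if k is None:
            raise KeyError(f"no component was assigned to {chromophore!r}")
        return self.A[k]


def svd_denoise(X: np.ndarray, energy_frac: float = 0.99) -> tuple[np.ndarray, int, np.ndarray]:
    """Low-rank truncation keeping the smallest rank whose cumulative squared
    singular values reach ``energy_frac`` of the total energy.

    Returns (X_lowrank, rank, singular_values); the rank is also the
    suggested NNMF component count.
    """
    if not 0.0 < energy_frac <= 1.0:
        raise ValueError("energy_frac must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.any(X):
        raise ValueError("cannot denoise an all-zero matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    energy = np.cumsum(s**2) / np.sum(s**2)
    rank = int(np.searchsorted(energy, energy_frac - 1e-12) + 1)
    rank = min(rank, s.size)
    X_lowrank = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    return X_lowrank, rank, s


def superpixel_subsample(
    stack: MultispectralStack,
    roi: np.ndarray,
    n_superpixels: int,
    compactness: float = 10.0,
) -> SuperpixelMap:
    """SLIC clustering of the wavelength-mean image over the ROI; each
    superpixel contributes its mean spectrum.  Deterministic given inputs."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.spatial_shape:
        raise ValueError("ROI shape does not match the stack")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    if not 1 <= n_superpixels <= n_roi:
        raise ValueError(f"n_superpixels must be in [1, {n_roi}] (ROI pixel count)")

    labels = np.full(stack.spatial_shape, -1, dtype=int)
    if n_superpixels == n_roi:
        labels[roi] = np.arange(n_roi)
    else:
        mean_img = stack.data.mean(axis=0)
        lo, hi = mean_img[roi].min(), mean_img[roi].max()
        norm = (mean_img - lo) / (hi - lo) if hi > lo else np.zeros_like(mean_img)
        seg = slic(
            norm,
            n_segments=n_superpixels,
            compactness=compactness,
            mask=roi,
            start_label=1,
            channel_axis=None,
        )
        ids = np.unique(seg[roi])
        ids = ids[ids > 0]
        remap = {int(v): i for i, v in enumerate(ids)}
        inside = roi & (seg > 0)
        labels[inside] = [remap[int(v)] for v in seg[inside]]
        # mask-edge pixels SLIC may leave unlabeled join their nearest label
        stray = roi & (labels < 0)
        if stray.any():
            from scipy.ndimage import distance_transform_edt

            _, (ri, ci) = distance_transform_edt(labels < 0, return_indices=True)
            labels[stray] = labels[ri[stray], ci[stray]]

    k = int(labels.max()) + 1
    n_wl = stack.data.shape[0]
    flat = stack.data.reshape(n_wl, -1)
    lab_flat = labels.ravel()
    inside = lab_flat >= 0
    sizes = np.bincount(lab_flat[inside], minlength=k).astype(float)
    sums = np.zeros((k, n_wl))
    for j in range(n_wl):
        sums[:, j] = np.bincount(lab_flat[inside], weights=flat[j, inside], minlength=k)
    mean_spectra = sums / sizes[:, None]
    return SuperpixelMap(
        labels=labels,
        n_superpixels=k,
        mean_spectra=mean_spectra,
        grid=stack.grid,
        sizes=sizes.astype(int),
    )


def _nndsvda(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic NNDSVD initialization, zeros filled with the data mean."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(s[0]) * np.abs(Vt[0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        nup, nun = np.linalg.norm(up), np.linalg.norm(un)
        nvp, nvn = np.linalg.norm(vp), np.linalg.norm(vn)
        mp, mn = nup * nvp, nun * nvn
        if mp >= mn and mp > 0:
            W[:, j] = np.sqrt(s[j] * mp) / nup * up
            H[j] = np.sqrt(s[j] * mp) / nvp * vp
        elif mn > 0:
            W[:, j] = np.sqrt(s[j] * mn) / nun * un
            H[j] = np.sqrt(s[j] * mn) / nvn * vn
    avg = X.mean()
    W[W <= 0] = avg
    H[H <= 0] = avg
    return W, H


def _spa_init(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Successive-projection (pure-sample) initialization: greedily pick the
    sample spectra with the largest residual norm after projecting out the
    already chosen ones, then seed abundances by NNLS.  Deterministic, and
    exact for separable data (every endmember present somewhere pure)."""
    R = X.astype(float).copy()
    rows = []
    for _ in range(k):
        j = int(np.argmax(np.linalg.norm(R, axis=1)))
        rows.append(j)
        u = R[j] / max(np.linalg.norm(R[j]), _EPS)
        R -= np.outer(R @ u, u)
    H = X[rows].copy()
    H = H / np.maximum(H.max(axis=1, keepdims=True), _EPS)
    W = np.stack([nnls(H.T, x)[0] for x in X])
    return np.clip(W, _EPS, None), np.clip(H, _EPS, None)


def nnmf_unmix(
    X: PixelSpectraMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
    init: str = "spa",
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Non-negative factorization X ≈ A_sub · S of sample spectra.

    Deterministic initialization (``seed`` is kept in the signature for API
    stability but neither init draws random numbers) followed by
    multiplicative Frobenius updates until the relative error improvement
    drops below ``tol`` or ``max_iter`` is reached.  ``init`` is "spa"
    (successive projection onto pure samples, default — resolves the
    rotational ambiguity toward endmembers actually present in the data) or
    "nndsvda" (non-negative double SVD, zeros filled with the data mean).
    Rows of S are normalized to unit maximum with the scale absorbed into
    A_sub.

    Returns (S, A_sub, info) where info carries the per-iteration
    reconstruction-error trace and the count of clipped negative inputs.
    """
    if isinstance(X, PixelSpectraMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(X.shape):
        raise ValueError(f"K={K} exceeds min(X.shape)={min(X.shape)}")
    n_neg = int((X < 0).sum())
    if n_neg:
        log.info("clipping %d negative entries before NNMF", n_neg)
        X = np.clip(X, 0.0, None)
    if not np.any(X):
        raise ValueError("cannot factorize an all-zero matrix")

    if init == "spa":
        W, H = _spa_init(X, K)
    elif init == "nndsvda":
        W, H = _nndsvda(X, K)
    else:
        raise ValueError(f"unknown init {init!r}")
    norm_x = np.linalg.norm(X)
    trace = [float(np.linalg.norm(X - W @ H))]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(X - W @ H))
        prev = trace[-1]
        trace.append(err)
        if prev - err < tol * norm_x:
            break

    scale = H.max(axis=1)
    scale[scale <= 0] = 1.0
    S = H / scale[:, None]
    A_sub = W * scale[None, :]
    info = {"error_trace": np.asarray(trace), "clipped_negatives": n_neg,
            "reconstruction_error": trace[-1] / max(norm_x, _EPS)}
    return S, A_sub, info


def project_abundances(
    stack: MultispectralStack, roi: np.ndarray, S: np.ndarray
) -> np.ndarray:
    """Per-pixel non-negative least squares of each ROI spectrum onto the
    endmember rows of S; returns (K, depth, lateral) maps, zeros outside."""
    roi = np.asarray(roi, dtype=bool)
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[1] != stack.data.shape[0]:
        raise ValueError("S must be (K, n_wavelengths) matching the stack grid")
    if np.any(~np.any(S, axis=1)):
        raise ValueError("S contains an all-zero endmember row")
    k = S.shape[0]
    h, w = stack.spatial_shape
    A_full = np.zeros((k, h, w))
    design = S.T  # (n_wavelengths, K)
    ys = stack.data[:, roi].T
    coefs = np.empty((ys.shape[0], k))
    for i, y in enumerate(ys):
        if not np.any(y):
            coefs[i] = 0.0
        else:
            coefs[i], _ = nnls(design, y)
    A_full[:, roi] = coefs.T
    return A_full


def assign_components(
    S: np.ndarray,
    grid: WavelengthGrid,
    lib: SpectraLibrary,
    band: tuple[float, float] = COLLAGEN_BAND_NM,
) -> dict[int, tuple[str, float]]:
    """Greedy one-to-one matching of endmembers to library chromophores by
    Pearson correlation.

    Collagen is matched on its detection band (default 880–970 nm, where
    its 930 nm peak stands clear of blood and water); every other
    chromophore is matched on the full grid.  Ties break by chromophore
    name order; components left without a chromophore are "unknown"."""
    S = np.asarray(S, dtype=float)
    n_comp = S.shape[0]
    names = sorted(lib.names)
    cand: list[tuple[float, str, int]] = []
    for k in range(n_comp):
        em = Spectrum(grid, S[k], f"endmember{k}")
        for name in names:
            ref = lib[name]
            try:
                if name == "collagen3":
                    r = pearson_similarity(
                        band_restrict(em, *band), band_restrict(ref, *band)
                    )
                else:
                    r = pearson_similarity(em, ref)
            except ValueError:
                continue  # constant spectrum on this band: unmatchable
            cand.append((r, name, k))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    assignment: dict[int, tuple[str, float]] = {}
    used: set[str] = set()
    for r, name, k in cand:
        if k in assignment or name in used:
            continue
        assignment[k] = (name, float(r))
        used.add(name)
    for k in range(n_comp):
        assignment.setdefault(k, ("unknown", math.nan))
    return dict(sorted(assignment.items()))
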