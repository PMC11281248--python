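# Methods

## Forward model and phantom generator

The simulator emulates a multispectral photoacoustic acquisition over the
NIR-I window (680–970 nm, 5 nm steps, 59 frames) with a co-registered
B-mode image. Per sub-skin pixel (z, x) and wavelength λ the initial
pressure is

    p(λ, z, x) = Γ · Φ₀ · exp(−μ_eff(λ) · d_mm(z, x)) · Σ_k c_k(z, x) ε_k(λ) + N(0, σ)

with Γ a Grüneisen-like efficiency (default 1), Φ₀ the surface fluence
(default 1), μ_eff(λ) the effective optical attenuation in 1/mm, d_mm the
depth below the per-column skinline, c_k non-negative chromophore
concentration maps and ε_k the unit-maximum library spectra. Pixels above
the skinline carry no tissue signal. The fluence model is deliberately a
1-D depth exponential per wavelength: it is analytically invertible, which
makes the decoloring stage exactly testable, and μ_eff is a pluggable
spectrum, so a more elaborate light-transport model can be substituted
without touching the pipeline. The default μ_eff is
`0.03 + 0.10·(HbO₂+Hb)/2 + 0.08·water` (≈ 0.03–0.2 /mm, soft tissue in
NIR-I); being built from blood and water absorption it is spectrally
non-flat, so coloring genuinely distorts deep spectra and the correction is
a meaningful step rather than a scalar gain.

### Reference spectra

No tabulated chromophore spectra ship with typical imaging systems, so the
package bundles a fixture CSV (`spax/data/reference_spectra.csv`, 59 rows)
of literature-shaped, unit-maximum spectra: collagen III peaking at 930 nm,
HbO₂ with a shallow 690 nm minimum rising toward 970 nm, Hb peaking at
760 nm, water nearly transparent below 900 nm with a steep rise toward its
975 nm band, and lipid with a narrow 925 nm peak. The simulator and the
unmixer share this library, so recovery tests are self-consistent and do
not hinge on literature accuracy; absolute amplitudes are absorbed into the
simulated concentrations (the analysis reports only relative abundances).

### Scene layout

`fibrosis_phantom` models liver parenchyma as a smooth positive
total-hemoglobin field (unit mean) split by a smooth SO₂ field in
0.55–0.85, with fibrosis as 5 focal Gaussian collagen deposits
(σ = 6–14 px) below an 8-px skinline at 0.1 mm/px. The default deposit
amplitude is 2.0 relative to the hemoglobin field — dense fibrotic scars
whose in-band signal is comparable to blood. Substantially weaker deposits
leave the collagen direction under the default 0.99 SVD energy threshold
(the positive blood-mix component alone holds >99% of spectral energy), at
which point the blind stage degenerates to a single mixed component; the
recovery tests therefore probe the regime the method is designed for, and
detecting trace baseline collagen is out of its scope. Noise is additive
Gaussian with σ set as a fraction of the noiseless peak (default 2%).
`simulate_progression` scales only the collagen map by per-visit factors
with fresh noise per visit. `so2_phantom` (HbO₂/Hb only, lateral SO₂ ramp
0.15–0.95 plus smooth perturbation) serves oximetry recovery tests. All
randomness flows from one integer seed through named `SeedSequence`
streams; every stage is bit-reproducible.

The B-mode companion is multiplicative gamma speckle (4 looks) scaled and
offset to hit a target ROI mean and mean local gray-level variance (the
scale is self-calibrated on the realized speckle field, so the first-order
targets are met within a few percent at ≥128² px), clipped to [0, 255].
Defaults are ROI mean 103.4 and local variance 135 — representative
baseline echogenicity/heterogeneity settings for rodent liver. It emulates
first-order statistics only: there is no point-spread function, no
depth-dependent attenuation of the echo field, and no anatomical texture,
so B-mode tests validate the feature extractors, not ultrasound physics.

## Pipeline stages and numerical choices

* **Skinline**: global Otsu threshold, first supra-threshold row per
  column, 1-D median smoothing (window 5). Columns with no echo get the
  image depth and a warning. Otsu was chosen because it is parameter-free
  and exactly reproducible.
* **Decoloring**: division by Φ(λ, z) with depth measured from the
  skinline (the tissue/background watershed), not the transducer. The gain
  exp(μz)/Φ₀ is capped (default 50×) so uncorrectable deep voxels cannot
  dominate the factorization; capped voxels are counted and logged.
* **Superpixels**: SLIC on the wavelength-mean image (min-max normalized
  over the ROI), masked to the ROI, compactness 10, default 200 segments.
  A single segmentation on the mean image keeps one coherent spatial
  partition; rare mask-edge pixels SLIC leaves unlabeled join their
  nearest segment. Requesting exactly one superpixel per ROI pixel
  degenerates to per-pixel spectra.
* **SVD rank selection**: smallest rank whose cumulative squared singular
  values reach `energy_frac` (default 0.99) of the total; the truncation
  denoises the matrix and the rank seeds the NNMF component count.
* **NNMF**: multiplicative Frobenius updates with an ε = 1e−12 guard,
  stopping when the per-iteration error improvement falls below
  `tol·‖X‖` (tol 1e−7) or at 500 iterations; the error trace is recorded
  and is non-increasing. Initialization is successive projection (SPA):
  greedily pick the sample spectra with the largest residual norm after
  projecting out prior picks, seed abundances by NNLS. SPA is
  deterministic and exact for separable data (every endmember present
  somewhere nearly pure, as in tissue with focal deposits); NNDSVDa
  initialization is available as an option but can settle on a rotated
  non-negative factorization of the same data — NNMF is not unique when
  spectra share baseline offsets. Endmember rows are normalized to unit
  maximum, scales absorbed into the abundances. Negative inputs (possible
  after SVD truncation) are clipped to zero with a logged count.
* **Abundance projection**: per-pixel NNLS against the endmember rows at
  full resolution; zeros outside the ROI.
* **Identification**: Pearson correlation of each endmember against each
  library spectrum — collagen on the closed 880–970 nm band (19 samples),
  others on the full grid — then greedy one-to-one assignment by
  descending correlation, ties broken by chromophore name; leftover
  components are "unknown". One-to-one matching prevents two components
  both claiming collagen.

## Quantification

* **Collagen correlation**: by default the ROI-mean decolored spectrum vs
  the collagen III reference, band-restricted; correlating the
  collagen-assigned endmember instead is a mode flag (both per-animal entry
  points are legitimate and the package exposes both).
* **Percent area**: 100·|{abundance > τ}|/|ROI|. τ defaults to Otsu on the
  map's ROI histogram; `fixed_frac` (τ = f·max) and absolute thresholds are
  available. For longitudinal series `analyze_progression` computes one
  pooled Otsu threshold over all visits of an animal: any per-map threshold
  is invariant to rescaling the map and would hide growth in collagen
  signal between visits — a shared detection threshold is what makes areas
  comparable across time.
* **SO₂**: HbO₂/(HbO₂+Hb) with hemoglobin-free pixels masked out of
  summaries (not zeroed). The summary is 100·mean over valid ROI pixels by
  default; an SO₂-positive-area mode is a flag, since either reading of
  "percent SO₂" is defensible. The pipeline's SO₂ source defaults to
  supervised NNLS onto the library HbO₂/Hb spectra ("reference" mode):
  blind NNMF components of spatially overlapping hemoglobin mixtures carry
  a rotational ambiguity that would alias into oximetry; using the blind
  HbO₂/Hb components is available as "unmixed" mode.
* **Ratio**: collagen percent area divided by percent SO₂ — collagen
  burden per unit tissue oxygenation.
* **B-mode features**: echointensity is the ROI mean gray level;
  heterogeneity is the mean over ROI pixels of the local population
  variance in a 5×5 window clipped to borders and to the ROI (global ROI
  variance as an alternate mode). Population (divisor n) variance
  throughout, fixed for reproducibility; local variance is the default
  because heterogeneity magnitudes of interest far exceed squared
  echogenicity spreads, consistent with variance units.
* **Longitudinal table**: mean ± sample sd (ddof 1, NaN for n = 1) per
  label across animals; rows ordered by an explicit label order or sorted
  labels, so the table is invariant to input order.

## Problem sizes in tests and the acceptance script

Full-scale recovery runs at 128×256 px × 59 wavelengths with 200
superpixels (seconds per stack); the four-animal × four-visit longitudinal
series uses 64×128 px replicates, which preserves every qualitative
behavior of the larger phantom while keeping the whole suite fast. The
oximetry phantom is 64×128 px.

## Known limitations

* The fluence model is 1-D exponential decay below the skinline; lateral
  fluence structure, scattering anisotropy, and multi-layer effects are not
  modeled. The interface accepts any μ_eff spectrum, and a Monte Carlo
  fluence map could replace the analytic Φ without changing the pipeline.
* The generator's noise is additive Gaussian and spatially white; real
  photoacoustic noise is partly structured (reconstruction artifacts,
  laser-energy jitter). Passing recovery tests therefore demonstrates
  algorithmic correctness, not in vivo performance.
* Blind separation needs the target chromophore to carry a visible share
  of spectral energy (see scene layout above); trace collagen below the
  SVD energy floor is reported as absent, not resolved.
* B-mode simulation reproduces first-order statistics only.
* Wavelengths outside 680–970 nm (e.g. NIR-II collagen bands) and molar
  extinction units are out of scope.
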