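# spax

Superpixel spectral photoacoustic unmixing for tracking collagen during
liver-fibrosis progression.

## The problem

Liver fibrosis is driven by collagen (particularly type III) accumulating in
the parenchyma. Spectral photoacoustic imaging (sPAI) acquires one image per
optical wavelength across the NIR-I window (680–970 nm in 5 nm steps, 59
frames) co-registered with B-mode ultrasound, and can in principle resolve
collagen by its absorption peak near 930 nm — a band where blood and water
absorb comparatively little. Two obstacles stand in the way:

* **spectral coloring** — overlying tissue attenuates light at a
  wavelength-dependent rate, so the spectrum measured at depth is a
  distorted version of the chromophore spectrum; and
* **unmixing** — collagen is a weak absorber mixed with dominant hemoglobin
  signal, so supervised fitting to assumed spectra is fragile.

This package implements a blind unmixing pipeline for such stacks:

1. **skinline segmentation** on the B-mode image (Otsu threshold, per-column
   first echo, median-smoothed) to locate the tissue surface;
2. **fluence correction (spectral decoloring)**: each voxel is divided by a
   modeled fluence Φ(λ, z) = Φ₀·exp(−μ_eff(λ)·z), with depth z measured from
   the skinline and a capped gain;
3. **superpixel subsampling**: SLIC clustering of the ROI on the
   wavelength-mean image; each superpixel contributes its mean spectrum;
4. **SVD denoising** of the superpixel-spectra matrix; the rank reaching a
   set energy fraction (default 0.99) also sets the number of components;
5. **NNMF**, X ≈ A·S with S, A ≥ 0, deterministic successive-projection
   initialization and multiplicative updates — endmember spectra plus
   abundances;
6. **NNLS projection** of every ROI pixel onto the endmembers for
   full-resolution abundance maps;
7. **identification**: each endmember is matched to a reference chromophore
   library (collagen III, HbO₂, Hb, water, fat) by Pearson correlation —
   collagen on its 880–970 nm detection band.

Downstream metrics per timepoint: Pearson correlation of the liver spectrum
with the collagen III reference, percent area of supra-threshold collagen
abundance, tissue oxygen saturation SO₂ = HbO₂/(HbO₂+Hb), the collagen-area
to SO₂ ratio, and first-order B-mode features (echointensity,
heterogeneity). A synthetic phantom generator with retained ground truth —
liver-like hemoglobin fields with focal collagen deposits, wavelength-
dependent depth attenuation, additive noise, and a speckled B-mode
companion — stands in for in vivo data and makes every stage testable
against known truth.

## Worked example

```python
import numpy as np
import spax

lib = spax.reference_library()                      # bundled chromophore spectra
spec = spax.fibrosis_phantom((128, 256), seed=1)    # collagen3 + HbO2 + Hb, 2% noise
stack, truth = spax.simulate_stack(spec, lib)

result = spax.unmix_stack(stack, lib=lib, n_superpixels=200, seed=1)
k = result.component_for("collagen3")
print("components:", result.n_components)
print("collagen endmember correlation (880-970 nm):", round(result.assignment[k][1], 4))
roi = stack.roi_mask
print("abundance map vs truth:", round(np.corrcoef(
    result.abundance_for("collagen3")[roi],
    truth.spec.concentrations["collagen3"][roi])[0, 1], 4))
```

prints

```
components: 2
collagen endmember correlation (880-970 nm): 0.9989
abundance map vs truth: 0.9887
```

i.e. the blind pipeline isolated an endmember whose band-restricted spectrum
is nearly identical to the collagen III reference, and whose per-pixel
abundance tracks the true collagen concentration map. Skipping the fluence
correction on the same stack drops the endmember correlation to 0.86 —
spectral decoloring is what keeps deep collagen recognizable.

The same analysis is scriptable from a shell:

```sh
spax simulate --seed 1 --out runs/sim          # 4 timepoints, collagen x (1, 1.5, 2, 3)
spax unmix --stack runs/sim/stack_t3.tif --roi runs/sim/roi.png --out runs/unmix
spax quantify --sim-dir runs/sim --out runs/quant    # longitudinal metrics.csv
spax report --metrics runs/quant/metrics.csv --out runs/report
```

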