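# paox — spectral photoacoustic oximetry of the placenta

`paox` is a tested Python re-implementation of an in vivo placental-oxygenation
analysis pipeline for multispectral photoacoustic (PA) imaging, built for
researchers studying placental ischemia (e.g. in the reduced uterine perfusion
pressure, RUPP, rat model of preeclampsia). Because animal image data cannot be
redistributed, the package ships a first-class synthetic-data module that
forward-simulates the whole study, so every stage of the analysis is verifiable
end to end against known ground truth.

## What it computes

A multispectral PA scan acquires one amplitude image per laser wavelength —
here 690 nm (deoxyhemoglobin absorption peak), ~808 nm (isosbestic point) and
950 nm (oxyhemoglobin dominant). Under the linearized PA generation model the
amplitude at pixel *x* is

    p(x, λ) = Γ · μₐ(x, λ) · Φ(λ),   μₐ = ln10 · (ε_HbO₂(λ) C[HbO₂] + ε_Hb(λ) C[Hb])

After dividing out the per-wavelength surface fluence Φ(λ), the package solves
the per-pixel linear least-squares system for the two hemoglobin
concentrations, averages them over a region of interest (the placental
border), and reports oxygen saturation

    sO₂ = C[HbO₂] / (C[HbO₂] + C[Hb])

Around that core it provides:

- **`paox.optics`** — hemoglobin extinction spectra (bundled 650–1000 nm
  table), interpolation, isosbestic search;
- **`paox.phantom`** — placental phantoms, the forward PA model, the
  two-cohort longitudinal study simulator (NP vs RUPP × gestational days
  14/16/18, 10 animals × 5 placentas), and synthetic H-DAB histology;
- **`paox.unmix`** — fluence correction, least-squares unmixing (with
  `clip_negative` or `nnls` handling of negative solutions), ROI sO₂;
- **`paox.render`** — the 255-step blue-to-red oxygenation colormap overlaid
  on the structural image with amplitude-scaled transparency;
- **`paox.ihc`** — optical-density transform, H-DAB color deconvolution and
  percent DAB-positive area (HIF-1α hypoxia staining readout);
- **`paox.stats`** — per-animal averaging, two-way repeated-measures (mixed)
  ANOVA with Bonferroni-corrected contrasts, Welch t-tests from printed
  mean ± SEM summaries, and noncentral-t power calculations.

## Worked example

```python
>>> from paox import (default_table, isosbestic_wavelength,
...                   make_placenta_phantom, forward_pa, unmix_roi)
>>> table = default_table()
>>> isosbestic_wavelength(table, 750, 850)   # nm; crossing sits just below 808
797.0
>>> truth, mask = make_placenta_phantom(so2=0.60, seed=0)  # 60%-saturated placenta
>>> scan = forward_pa(truth, table, noise_sd=None, seed=0) # 20 dB SNR, 3 wavelengths
>>> res = unmix_roi(scan, table, mask)
>>> round(res.roi_so2, 4), res.n_roi_pixels, res.n_clipped_pixels
(0.5964, 459, 0)
```

The recovered ROI saturation (59.6%) sits within noise of the 60% ground
truth; no pixel needed negative-concentration clipping. The statistics stage
reproduces the cohort-level significance calls from printed summaries, e.g.
maternal weight gain 25.112 ± 2.92 g (n=10) vs 10.40 ± 1.09 g (n=10):

```python
>>> from paox import t_from_summary, power_two_sample
>>> t, df, p = t_from_summary(25.112, 2.92, 10, 10.40, 1.09, 10)
>>> round(t, 2), round(p, 5)                 # Welch t-test: p < 0.001
(4.72, 0.00056)
>>> round(power_two_sample(1.569, 10, sides=1), 3)  # a priori design power
0.958
```

A CLI mirrors the library (`paox simulate-cohort`, `paox unmix`,
`paox overlay`, `paox ihc`, `paox stats`); see `paox --help`.

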