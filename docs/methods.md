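# Methods

This note documents the models, defaults and design choices behind `paox`,
and what the synthetic validation does and does not demonstrate.

## Hemoglobin spectra

Spectral unmixing presupposes known molar extinction spectra ε_Hb(λ),
ε_HbO₂(λ). The bundled file `paox/data/hb_extinction_synthetic.csv` is a
*synthetic* tabulation: anchor points transcribed from the standard compiled
whole-blood hemoglobin spectra (the Gratzer/Kollias compilation as
distributed by the Oregon Medical Laser Center), PCHIP-interpolated to a
2-nm grid over 650–1000 nm. It reproduces the qualitative structure that
matters for three-wavelength oximetry — Hb dominant at 690 nm (ε_Hb/ε_HbO₂
≈ 7), HbO₂ dominant at 950 nm, and an isosbestic crossing near 797 nm — but
individual coefficients are approximate, so it is suitable for simulation
and for validating inversion code, not for absolute dosimetry. Any CSV with
columns `wavelength_nm,eps_hbo2,eps_hb` can be substituted throughout.

Interpolation between grid points is linear; at ≤ 2 nm spacing the error of
higher-order schemes is far below every tolerance used here. The isosbestic
search scans a dense (0.1 nm) interpolated grid and breaks ties toward the
smaller wavelength, making it deterministic.

Note that in compiled spectra the true crossing sits ~10 nm below the
nominal 808 nm isosbestic wavelength used by common PA instruments; at
808 nm the bundled table's relative ε gap is ~17%. Tests therefore assert
near-equality (< 2%) at the *table's own* crossing and only a bounded gap
(< 20%) at 808 nm.

## Forward model and phantoms

The forward simulation uses the linearized photoacoustic generation model
p = Γ·μₐ·Φ with μₐ = ln10·(ε_HbO₂ c_HbO₂ + ε_Hb c_Hb) and additive
zero-mean Gaussian amplitude noise. Γ (Grüneisen parameter × system gain)
is fixed to 1 in arbitrary units: saturation is a concentration ratio and
is invariant to any global scale, so concentrations throughout the package
are relative, never molar.

Fluence Φ(λ) defaults to `surface_only`: the per-wavelength surface pulse
energy density (default 11–18 mJ/cm², inside the 10–20 mJ/cm² instrument
range) with no depth term, matching an analysis whose only fluence
compensation is laser-energy normalization. A `beer_lambert_depth` variant
(Φ·exp(−μ_eff·depth)) exists to study the bias introduced when depth
attenuation is real but uncorrected; it is never the default.

Phantoms place an elliptical "placenta" (~8 × 4 mm, jittered per placenta)
at mid-depth in a 30 × 22 mm field sampled at 128 × 96 pixels (0.234
mm/pixel), below a 1-mm coupling layer; surrounding tissue carries 20% of
the placental hemoglobin. These geometry defaults are plausible stand-ins —
no placental size/depth statistics were available to fit them. Optional
smooth texture modulates total hemoglobin by ≤ 10% without touching
saturation. The default noise level is defined as 20 dB amplitude SNR in
the placenta at the wavelength nearest 808 nm, a level visually comparable
to in vivo PA data; it is recomputed per scan from the noise-free signal,
so it is deterministic given the seed.

## Simulated cohort

The cohort simulator emulates the two-group longitudinal design: groups NP
and RUPP, gestational days 14/16/18, 10 animals per group, 5 placentas per
animal (300 scans). Group/day means are: NP = 60% sO₂ everywhere; RUPP =
60% at GD14 (pre-surgery), 12% relative decrease at GD16, and 9% at GD18.
The GD18 value encodes the qualitative "slight recovery" of the deficit;
its magnitude is a configuration default, not a measured claim. Animal-day
means are drawn Normal(cell mean, 0.03) and placenta truths
Normal(animal mean, 0.03), clipped to [0.02, 0.98]; the 0.03 standard
deviations give a GD16 group separation of d ≈ 2 at the animal level,
comfortably significant at n = 10 (the a priori design power for d = 1.569
at n = 10 is 0.958 one-sided). All randomness derives from one master seed
through per-cell `SeedSequence` spawn keys, so streams are independent and
every rerun is byte-identical.

What the simulation does *not* emulate: acoustic propagation and
transducer effects (bandwidth, beamforming, speckle physics), motion and
breathing, skin/suture artifacts, depth-dependent fluence by default, and
any correlation of an animal's mean across gestational days. Passing
recovery tests therefore demonstrates the correctness of the inversion and
statistics code under the stated image model — not the accuracy of
photoacoustic oximetry in tissue.

## Unmixing

Frames are divided by their surface fluence (idempotent via a `corrected`
flag), then every pixel is inverted by linear least squares against the
ln10-scaled extinction matrix; the 3 × 2 system at 690/808/950 nm has
condition number ~3 and is rejected above 10⁸. Per-pixel concentrations are
averaged over the ROI mask and sO₂ is formed from the ROI means, so the
reported value weights pixels by area, not amplitude.

Negative per-pixel solutions (possible under noise) are handled by policy:
`clip_negative` (default) zeroes the negative component before averaging —
the minimal rule that keeps sO₂ in [0, 1] — while `nnls` re-solves offending
pixels under a nonnegativity constraint; both leave already-nonnegative
pixels untouched, and the count of clipped components is reported. How the
original analysis treated negative solutions is unknown; this is a
documented policy choice, not a claim about that code. Pixels whose total
concentration is ≤ 0 after clipping have undefined saturation: they are
excluded from the sO₂ map (rendered transparent) but still counted in the
ROI pixel total, and an ROI whose mean total is ≤ 0 raises a
degenerate-input error.

At the default SNR the ROI estimator is unbiased to well under 0.01 sO₂
(verified over hundreds of seeded phantoms at truths 0.3/0.5/0.7), and a
single 60%-truth placenta is recovered within ±0.02.

## Rendering

The oxygenation colormap has exactly 255 entries, a straight RGB ramp from
blue (0,0,255) to red (255,0,0); only the endpoints are part of the display
convention — intermediate hues (through dark purple) are this package's
choice. Overlay transparency is the fluence-corrected amplitude divided by
its 99th in-mask percentile (clipped to [0, 1]); the percentile reference
makes full opacity robust to isolated hot pixels. Undefined-sO₂ pixels and
everything outside the mask are fully transparent. Rendering is a pure
function: identical inputs give identical PNG bytes.

## Histology quantification

Brightfield slides are converted to optical density per channel
(OD = −log₁₀(max(I,1)/255); the 1-count floor keeps saturated-dark pixels
finite) and deconvolved with the standard Ruifrok–Johnston H-DAB stain
matrix (hematoxylin [0.650, 0.704, 0.286], DAB [0.268, 0.570, 0.776],
nonnegative residual third vector). The readout is the percent of
placental-mask pixels whose DAB amount exceeds 0.15 OD — a default chosen
to separate generated DAB blobs from hematoxylin bleed-through in the
synthetic fixtures, exposed as a flag since no threshold was reported for
the original analysis. Manual border segmentation is replaced by a mask
file input. The synthetic slide generator composes images in OD space with
an exactly known DAB-positive pixel count, so recovery is testable to ±2
percentage points across 5–90% truth fractions including 8-bit
quantization.

## Statistics

The experimental unit is the animal: placenta-level values are averaged per
(animal, day) before inference; missing cells are flagged, never imputed.
The primary model is a two-way mixed ANOVA (between factor group, within
factor gestational day, subject = animal), computed via `pingouin`'s
`mixed_anova` and cross-checked in tests against closed-form balanced
split-plot sums of squares. Sphericity correction is off by default (the
per-day contrasts of interest are unaffected; Greenhouse–Geisser is
available through `pingouin` directly). Per-day group contrasts use Welch
t-tests with Bonferroni adjustment across the three days; within-group
day-pair comparisons use paired t-tests with the same adjustment.
Degenerate zero-variance inputs report p = 1 by convention, and all
p-values are floored at 10⁻³⁰⁰ to avoid printing zeros.

Summary-statistics reanalysis (`t_from_summary`) uses Welch rather than
pooled t because printed SEMs differ markedly between groups; every
significance bound checked here holds under either choice. Power is the
exact noncentral-t power of a two-sample test (noncentrality d·√(n/2),
df = 2n−2); for d = 1.569, n = 10 the one-sided value is 0.958 and the
two-sided 0.912 — the sidedness behind the published figure is not stated,
so tests bracket it rather than assert one convention.

## Problem sizes

The validation suite runs the full 300-scan cohort once at 128 × 96 pixels
(a few seconds), property suites on 48 × 64 phantoms, and the ANOVA
type-I-error calibration on 2000 simulated null cohorts. The GD16
relative-decrease estimator has a sampling standard deviation of ≈ 2.4
percentage points under the default design (10 animals, SDs above), so
single-run values typically fall within ~±2 points of the 12% design value
but can occasionally land outside; the estimator is unbiased (mean 11.95
over 200 master seeds).
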