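# Methods

This note documents the models, conventions and numerical choices behind
`ecllquant`, and what validation on synthetic data does and does not
demonstrate.

## pH-front segmentation

**Model.** Electrolysis produces an acid front (anode, orange under the
halochromic dye) and a base front (cathode, blue) on the cut tissue surface.
The spatial extent of each front is quantified, not its pH value. A
user-supplied ROI inside each band defines that band's color population; the
image is segmented by Euclidean distance in CIE 1976 L\*a\*b\* space, where
Euclidean distance approximates perceived color difference. Because the ROI
statistics are re-estimated per image, moderate lighting and dye-intensity
shifts cancel out — no fixed reference colors exist anywhere in the package.

**The one-SD retention rule.** For ROI pixels with distances to the ROI mean
color having mean m and SD s, a pixel anywhere in the image is retained when
its distance d satisfies d ≤ m + k·s. The default k = 1 keeps the ROI's own
color population plus contiguous similar pixels; it is the only reading of a
"one SD" cutoff that yields non-empty masks (removing pixels both above and
below one SD would remove everything). k is exposed as `sd_multiplier`.

**Color convention.** sRGB companding, the 7-decimal IEC 61966-2-1
linear-RGB→XYZ matrix, and CIE 1976 L\*a\*b\* with the reference white taken
as the XYZ of sRGB (1,1,1). That self-consistent choice makes pure white map
exactly to (100, 0, 0); nominal D65 tristimulus values differ from the matrix
white only in the 7th decimal. The conversion is implemented directly
(vectorized, ~15 lines) because library conversions carry a rounded-matrix /
nominal-white mismatch of ~2.5×10⁻³ in a\*/b\* that breaks exact white
neutrality; a test cross-checks against scikit-image at 5×10⁻³ and against a
scalar closed-form oracle at 10⁻⁹.

**Distance statistics** use the population SD (ddof = 0). The difference from
the sample SD is negligible at realistic ROI sizes but must be pinned for
reproducibility.

**Mask cleanup.** Interior holes are filled with a 4-connected background
fill; 8-connected components smaller than `min_component_px` (default 25 px,
≈ 0.06 mm² of debris at 0.05 mm/px) are removed. The operation is idempotent.

**Width metric.** Mean count of mask pixels per *occupied* row × scale.
Rows without mask pixels are excluded so the result is independent of image
padding; an empty mask reports width 0 rather than erroring. The metric is
translation-invariant and invariant (to one boundary pixel per row) under
resolution doubling with scale halving.

**ROIs** are coordinates in config or CLI flags, not interactive clicks, so
every run is reproducible from its logged parameters.

## Fluorescence particle quantification

Per channel: median filter of radius 1 (3×3 — the standard despeckle
operation) → explicit numeric threshold (recorded in provenance; "user
defined" thresholds are deliberately replaced by config values for
reproducibility) → Euclidean-distance-transform watershed → per-particle
pixel counts × scale². Watershed seeds are local maxima of the distance
transform with a minimum separation of 5 px; because that suppression is
global, every 8-connected component is guaranteed at least one seed (its
distance-transform argmax) so no foreground pixel goes unlabeled. Watershed
flooding uses 8-connectivity to match the component convention.

A Bodipy (lipid) particle is classified as an adipocyte when at least
`min_overlap_px` (default 1) nuclear-mask pixels fall inside its label
region, else as a free lipid droplet — presence/absence of nuclear staining
is the defining rule, so the minimal overlap is the natural default.
Collagen second-harmonic signal can contaminate the nuclear channel as
elongated fibrils; `suppress_elongated` (major/minor axis ratio > 3, off by
default) removes them.

Thermography: the trace is the per-frame mean over an ROI; the maximum rise
is referenced to the first frame, with convenience flags at 1 °C (the ceiling
observed at treatment voltages ≤ 6 V) and 5 °C (resistive heating around
10 V).

## Electrochemical dosimetry

* **Charge**: trapezoidal integration of the monitored current — exact for
  piecewise-linear traces, second-order otherwise.
* **Water budget**: m = Q/F · ν · M(H₂O) with F = 96485 C/mol,
  M = 18.015 g/mol. ν defaults to 0.5 waters per electron (net electrolysis
  2 H₂O → 2 H₂ + O₂ consumes 2 H₂O per 4 e⁻); ν = 1 selects the cathode-only
  half-reaction bookkeeping. The inverse (charge for a given mass) supports
  consistency bounds.
* **Lysis inversion**: f = [K⁺]_released / [K⁺]_intracellular with the
  intracellular reference 130 mM (measured on homogenized + sonicated
  tissue). Default geometry: 3 mL tissue, 3 electrodes, 12 mm insertion
  depth, 3 mm spacing, 1:10 assay dilution. Released concentrations above
  130 mM warn rather than error (noisy inputs can exceed the reference).
  Cylinder radius r = √(V/(π·d)) with V in µL ≡ mm³.
* **Saponification**: h = c_treated / (c_positive · V_pe/V_sample) with
  V_pe the *unrounded* per-electrode volume recomputed from the potassium
  data (146.15 µL, 46.15 µL) rather than rounded table prints — this
  bookkeeping reproduces both published fractions (~40 %, ~48 %); the ±2 µL
  check tolerance absorbs table rounding (47 vs 46.15, 61 vs 61.5). The
  headline fraction does not subtract the 1.4 mg/L untreated-tissue glycerol
  background (matching the published numbers); `subtract_background=True`
  provides the corrected variant. Fractions above 1 are flagged, not
  clamped.
* **Calibration**: ordinary least squares reading = slope·conc + intercept
  via `scipy.stats.linregress`, inverted for prediction; r² reported.
  Instrument-side spectroscopy details (emission-line choice, background
  correction) are out of scope — the module starts from
  (concentration, reading) pairs.

## Synthetic data generator

All validation inputs are generated with known truth, seeded through numpy's
PCG64 (`default_rng`); the same seed is bit-reproducible, and each generator
emits a key=value truth sidecar.

* **pH maps**: two vertical color bands (package LAB constants chosen for
  dye-like contrast: orange ≈ (62, 35, 55), blue ≈ (45, 0, −45), tissue
  background ≈ (72, 14, 16)) centered on electrode positions 3 mm apart, at
  0.05 mm/px on a 240×400 canvas, with i.i.d. Gaussian LAB noise (default
  SD 2). The generator warns when color separation < 5× noise SD. Bands are
  rectangular; real fronts taper with depth, which the row-averaged width
  metric absorbs, so the taper option defaults off. Fronts wider than the
  electrode spacing physically merge where acid meets base, so
  width-recovery experiments (`make_recovery_ph_truth`) widen the spacing to
  (w_a + w_c)/2 + 1 mm when needed to keep both bands resolved.
* **Fluorescence fields**: non-overlapping disks (radius 8–14 px) placed by
  rejection sampling on a 256×256 canvas, 30 nucleated + 20 anucleate by
  default; nuclear dots of radius 3 px; Calcein rendered for the live
  fraction, EthD-1 for dead nucleated cells; Poisson photon noise (200
  photons at unit intensity) plus Gaussian read noise (SD 0.02).
* **Current traces**: 1 Hz sampling with multiplicative Gaussian noise; the
  expected integral is mean current × duration.
* **Assay readouts**: K⁺ released = f·130 mM·(1+ε) and glycerol =
  h·72 mg/L·(V_pe/V_sample)·(1+ε), ε ~ N(0, cv), with positive and negative
  control rows.

**What passing on synthetic data shows — and not.** Truth recovery
demonstrates the numerics of segmentation, watershed and the algebraic
inversions under the stated noise models. It does not demonstrate robustness
to real-tissue artifacts: uneven illumination beyond what per-image ROI
statistics absorb, dye pooling, out-of-focus or overlapping cells, collagen
autofluorescence beyond the simple fibril model, or electrode shadowing.

## Problem sizes used in validation

pH-width recovery uses 20 maps at 240×400 px spanning true widths
1.5–4.5 mm (measured mean absolute error ≈ 1 %); particle recovery uses 10
fields of 50 cells; assay recovery uses 100 replicates at cv = 0.1; the
charge-budget example integrates a 5 mA, 300 s trace (≈ 1.5 C, ≈ 140 µg of
water — inside the < 160 µg regime typical of these doses).

## Known limitations

* No electrode auto-localization, pH estimation from color, 3-D
  segmentation, reaction–diffusion or thermal modeling — the package
  quantifies, it does not simulate.
* The width metric assumes the fronts are roughly vertical in the image
  (insertion surface on top); strongly oblique fronts would need rotation
  first.
* Statistical comparisons between conditions (ANOVA etc.) are out of scope;
  the package emits tidy CSV tables any stats tool can consume.
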