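# Methods

This note documents the model implemented by `adiposeat`, its parameters,
the synthetic data generator used for validation, and the numerical
design decisions that shape the results.

## Coordinate conventions

All images are single sagittal slices `data[row, col]`:

* row 0 is the most superior row; rows increase inferiorly;
* col 0 is the most anterior column; columns increase posteriorly;
* `height_mm = (n_rows − 1 − row) · row_spacing` is measured upward from
  the inferior image edge (the side of the planar receiver coil under the
  seat cushion); `ap_mm = col · col_spacing`.

A pixel belongs to a mm-defined region when its **center** satisfies the
region predicate; mm intervals widened by a margin are closed on both
ends.

## Coil-gradient correction

Surface-coil reception attenuates signal with distance from the coil
plane. The model is an additive vertical falloff

    f(h) = a · (h + y0)^b + c

where `h` is height above the inferior image edge, `y0` the offset of the
effective coil plane below that edge, and `c` the flat tissue baseline.
Calibration uses a scan of a homogeneous fluid-filled ball: the fit
minimizes least squares between `f` and the per-height in-mask mean
intensities (`scipy.optimize.curve_fit`, multistart over `y0` and `b`,
bounds `b ∈ [−4, 4]`, `y0 ∈ [0.01, 1000]`). At least 10 distinct heights
are required. Correction subtracts `f(h)` per row and adds back the
image-height mean of `f`, so corrected images keep their overall
brightness; the subsequent effect sizes are invariant to that constant.

**Identifiability.** On a noiseless phantom all four parameters are
recovered to machine precision. Under realistic noise (SD 50 on a base
of 1800) the raw `(a, b, y0)` triple is *not* identifiable to within a
few percent: a Cramér–Rao analysis of this geometry gives a best-case
relative SD of ~10–20% for `a` because the three parameters trade off
along a likelihood ridge while leaving the curve over the imaged heights
nearly unchanged. The quantity the pipeline actually uses — the
mean-centered curve over the data-supported heights — is well
identified and is recovered to ≈1.2% mean (≤5% max) relative RMS across
20 noise seeds. Validation therefore asserts raw-parameter recovery only
for noiseless data and curve-level recovery for noisy data.

## Landmark and regions

* **IT peak**: the most inferior ischium pixel; ties are resolved to the
  floor of the tied columns' mean (rounding toward anterior).
* **Subcutaneous band**: every subcutaneous-fat (SubQF) pixel at or
  inferior to the point 10 mm superior to the peak.
* **Under the ischium**: band pixels whose AP position lies within the
  ischium's AP footprint (its extent within the band's height range)
  widened by 5 mm on each side, closed interval. **Surrounding** is the
  rest of the band; the two partition the band exactly.
* **IMAT reference adipose**: every SubQF pixel strictly posterior to the
  peak and inferior to the gluteus maximus' inferior boundary at its
  column; columns the gluteus never reaches are excluded.

Both effect sizes are Cohen's-d-style standardized mean differences with
the (n−1)-weighted pooled SD: SubQF = d(surrounding, under), IMAT =
d(reference adipose, gluteus).

A secondary **midpoint comparator** estimates the IMAT *fraction*
directly: the threshold is the midpoint of the reference-adipose mean
and the modal gluteus intensity below that mean; the fraction is the
share of gluteus pixels at or above the threshold. When almost no
gluteus pixels lie below the adipose mean (fully infiltrated muscle) the
result is flagged `degenerate` instead of silently returned.

## Biomechanical measures

* **Bulk tissue thickness**: mean vertical depth from the bone's
  inferior boundary to the bottom of the SubQF mask (skin included),
  over every bone-containing column within ±25 mm AP of the landmark.
* **Sagittal radius of curvature**: a Taubin algebraic circle fit to the
  per-column inferior bone contour restricted to ±25 mm of arc length
  from the contour point nearest the landmark. The Taubin fit is
  deterministic and initialization-free; collinear input yields a
  flagged infinite radius.

**Quantization limit.** A 50-mm chord on an ~84-mm circle rises only
~4 mm, i.e. ~4 gray levels of contour height in a 1-mm mask. Rasterizing
the arc therefore biases the fitted radius upward by roughly 10%
(up to ~19% across geometries) even on noiseless data, while the circle
fit itself is exact to 1e-6 on true circle points. Mask-derived radii
are validated to a 20% band and should be interpreted with that
resolution limit in mind.

## Synthetic data generator

The generator renders, from a single integer seed:

* **Phantom**: circular homogeneous region (radius 0.42 of the field of
  view, default 280×280 mm) at base intensity 1800, plus the gradient
  field and optional Gaussian noise.
* **Subject slice** (default 160×170 px at 1 mm): an ischium wedge whose
  inferior contour is an arc of `it_radius_mm`; a gluteus ellipse
  (semi-axes 18×30 mm) superior/posterior to the peak; a subcutaneous
  apron whose flat skin line is placed so the mean bone-to-skin depth
  over the 50-mm window equals `tissue_thickness_mm`. Compartment means
  default to fat 2022, posterior reference depot 1517, muscle 1324, bone
  400, background 80, with within-tissue texture (SD 150). A fraction
  `imat_fraction` of gluteus voxels is replaced by fat-like intensities.
  The under-ischium band is then shifted so the noiseless standardized
  contrast equals `subqf_contrast` *exactly*, and the gradient and noise
  are applied last. Ground truth records the exact region pixel sets,
  the gradient field and the pre-gradient image.
* **Cohort**: per-group parameter distributions (no-PrI vs PrI history)
  with SubQF contrast 0.21±0.56 vs 0.58±0.45, IMAT fraction 0.06±0.05 vs
  0.11±0.06 plus a complete-infiltration probability of 4/21 vs 3/22,
  thickness 17.1±7.1 vs 12.5±3.9 mm, radius 93.9±44.7 vs 73.6±27.5 mm,
  and covariates (years of wheelchair use, BMI, hip breadth, spasms,
  with realistic missingness). IMAT fraction increases mildly with years
  of use and decreases with spasms, giving the generator a recoverable
  correlation structure.

**Realism limits.** The generator produces a stylized 2D geometry — a
single bone wedge, one elliptical muscle, a flat skin line — not a
deformable anatomical model. Texture is i.i.d. Gaussian within
compartments; there is no partial-volume blur, chemical shift, or motion
artifact. The reference adipose depot partially overlaps the
under-ischium band posterior to the IT (anatomically plausible), which
lowers the effective reference mean; as a consequence the
partial-infiltration IMAT effect size crosses zero near fraction ≈0.2
rather than at the naive intensity-midpoint fraction ≈0.28. The
population-level distributions keep typical subjects well inside the
positive regime, with complete infiltration modeled as a separate
probability mass that produces strongly negative values.

## Cohort statistics

* Two-group comparisons use one-way ANOVA, which for two groups is
  algebraically the pooled two-sided t test; the identity `F = t²` is
  asserted internally on every call. The difference CI is the
  pooled-variance t interval. Groups with zero within-group variance are
  handled by the limit of the test (equal means → F = 0, p = 1;
  different → F = ∞, p = 0).
* Correlations are Pearson over pairwise-complete rows (≥3 pairs
  required; zero variance raises a typed error).
* The **exclusion rule** removes subjects with IMAT effect size < 0
  (complete fat infiltration) before re-running the group comparisons;
  the boundary value 0 is kept and the removed count is logged.
* No multiple-testing adjustment is applied; p values are raw, as in an
  exploratory analysis, and each result carries its own n.

Monte-Carlo calibration (500 replicate parameter-level cohorts of
21 + 22): the 95% CI of the SubQF group difference covers the true value
−0.37 in ≈95% of replicates, and the rejection rate under identical
group distributions is ≈5%.

## Design decisions

* **Calibration at the parameter level.** Statistical calibration draws
  cohort parameters without rendering images, which isolates the
  statistical machinery from rendering variance and runs in seconds.
  The rendered end-to-end path is validated separately (noiseless
  round trip to 1e-6; a full rendered 43-subject cohort recovers the
  generated group difference with the correct sign).
* **mm-anchored geometry.** All generator anchors are in millimetres, so
  changing pixel spacing changes resolution, not anatomy; region rules
  are likewise spacing-aware and validated at 1 mm and 2 mm.
* **Exact contrast by construction.** The post-hoc under-band shift
  makes the noiseless generative contrast exact rather than approximate,
  turning the end-to-end round trip into a machine-precision test.
* **Typed errors.** Degenerate inputs raise typed exceptions
  (`RegionError` naming the empty region, `UndefinedStatisticError` for
  zero-variance statistics, stage-tagged `StageError` in the pipeline)
  instead of returning silent NaNs; flagged degenerate results
  (midpoint comparator, circle fit) carry an explanatory note.

## Limitations

* 2D single-slice analysis; no volumetric extension.
* Segmentations are taken as given; no automatic segmentation.
* The synthetic cohort mirrors the *scale* of a clinical population but
  is not a substitute for patient data; absolute cohort statistics from
  simulations should not be quoted as clinical findings.
* Mask-derived curvature carries the ~10% rasterization bias described
  above at 1-mm resolution.
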