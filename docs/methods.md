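# Methods

This note documents the models, algorithms and design choices behind
`headcirc`: what each stage assumes, which parameters matter, what the
synthetic generators do and do not emulate, and where the numerics could
bite.

## The measurement model

A head photographed roughly face-on projects to an approximately
elliptical outline. The pipeline therefore models the head contour as an
ellipse and reports the circumference of that ellipse, scaled from pixels
to centimetres by a circular reference object of known diameter lying in
(approximately) the same plane as the head. The operator supplies four
landmark points — top, bottom and the two outermost lateral edges — which
act as strong priors on the ellipse's extremes.

Assumptions, in decreasing order of importance:

* the head outline is well-approximated by an ellipse (true for the
  occipitofrontal silhouette at the measurement plane; violated by hair
  volume, which is exactly the error source that motivates landmarks);
* the reference object is coplanar with the measured contour — any depth
  offset scales the measurement by the ratio of distances;
* out-of-plane camera tilt is small. Tilt forshortens one axis of the
  projected ellipse; a tilt of angle φ scales the axis by cos φ, so a
  14° tilt (cos φ ≈ 0.97) already moves a 42.5 cm circumference by about
  half a centimetre. This is the dominant real-world confounder.

### Segmentation

Foreground = pixels whose RGB distance to the background exceeds 0.12 (on
a 0–1 scale), with the background estimated as the median color of a
3-pixel image border; the mask is closed with a 3 px disc. Each connected
component's subpixel contour (marching squares at level 0.5) is fitted
with an ellipse, and the component is admitted as "oval" only if the RMS
fit residual is at most 5% of its equivalent radius √(A/π). The largest
admitted component is the head; ties break toward the lower residual.
The 5% gate is deliberately loose: it must pass real, slightly non-elliptic
heads while rejecting polygons and elongated clutter. The reference disc
also passes the gate (a circle is an ellipse) but never wins on area under
any sane composition.

### Ellipse fitting and landmark fusion

The fit is the numerically stable two-block formulation of the direct
least-squares conic fit with the ellipse constraint 4AC − B² = 1, solved
as a 3×3 eigenproblem after centering and scaling the points. It is exact
on noiseless data and has no iteration to tune. Residuals are Sampson
(gradient-normalized algebraic) distances — a first-order approximation of
orthogonal distance that is cheap and accurate near the curve.

Fusion re-runs the same fit over the contour plus the four landmarks with
per-point weights: 1 for contour points, 100 for each landmark. The weight
of 100 makes four landmarks carry the influence of 400 contour points —
comparable to the whole contour of a typical head at 20 px/cm (~850
points) — so landmarks correct gross segmentation errors (occlusion, hair)
while the contour still determines orientation and fine shape. With
landmarks on the fitted ellipse the refit is a fixed point by
construction.

### Scale and perimeter

The reference is detected by an HSV window (default: hue 0.50–0.78,
saturation ≥ 0.35, value ≥ 0.20 — a saturated blue disc) and gated on
circularity 4πA/P² > 0.85 with the Crofton perimeter estimate; its
area-equivalent diameter is robust to boundary aliasing. `px_per_cm` is,
definitionally, detected diameter over known diameter.

The reported circumference is the Ramanujan-II perimeter of the fused
ellipse, not the raw contour arc length: a rasterized contour overmeasures
arc length systematically (by ~5% in the worked README example), while the
ellipse perimeter is stable under re-rasterization. Ramanujan II was
chosen over series or iterative (AGM) evaluations because its relative
error is below 10⁻⁷ for aspect ratios up to 3 — far below every other
error source — and it is a closed form. The adaptive-quadrature arc-length
integral is kept in the package as the exact reference (and supplies the
phantom ground truth); the raw arc length is exposed on the result object
as a diagnostic.

Degenerate inputs: b = 0 is accepted by the perimeter functions as a
sanity check (true perimeter 4a; Ramanujan gives 3.9984a, −0.04%);
negative axes, a < b, fewer than 5 contour points, and collinear points
raise typed errors.

## The phantom generator

`render_phantom` draws, at a configurable scale (default 20 px/cm on an
800×600 canvas): a skin-tone head ellipse (default semi-axes 7.5 × 6.0 cm,
circumference 42.54 cm — a typical infant head) with 5% multiplicative
speckle emulating hair texture and a 4×-supersampled anti-aliased
boundary; a saturated blue reference disc (default 3.0 cm, the size of a
large bottle cap); optional gray convex distractor polygons placed away
from head and reference; and additive Gaussian pixel noise (default SD 2
on the 8-bit scale; the acceptance protocol uses 5). Out-of-plane tilt is
modeled as a multiplicative foreshortening of the rendered minor axis
(`foreshorten`, default 1.0); the ground-truth circumference always refers
to the untilted head, so foreshortening is a genuine error source rather
than a relabeling. One seeded generator drives all randomness; identical
specs give byte-identical PNGs.

What the phantom does **not** emulate: perspective and lens distortion,
shading and specularity, background clutter that touches the head, hair
that overhangs the outline, partial occlusion by hands, and any
depth offset between reference and head plane. Passing tests on phantoms
therefore demonstrate the geometry, calibration and statistics are
correct, and bound the algorithmic noise floor — they do not certify
clinical accuracy, where the unmodeled confounders dominate.

`simulate_rater_study` draws from the standard two-way additive model
HC_ijr = T_i + b_j + e_ijr with T_i ~ N(μ, σ_s²), fixed rater biases b_j
and rater-specific errors e_ijr ~ N(0, σ_j²). Defaults (μ = 45 cm,
σ_s = 2 cm, 37 subjects, two raters, one repeat) mirror an infant cohort
of the first 18 months of life. The implied ICC(2,1) is
σ_s² / (σ_s² + σ_b² + mean σ_j²), with the bias spread entering as rater
variance — the closed-form truth the estimator is checked against.

## Agreement statistics

* **ICC**: computed from the two-way ANOVA mean squares of the subject ×
  rater cell matrix (duplicate cells averaged; missing cells are an error
  naming the holes, not silently dropped). The default form is ICC(2,1) —
  two-way random effects, absolute agreement, single measurement — because
  a method-comparison study asks about absolute HC values, where a
  calibration offset between raters must count against reliability.
  Consistency (3,1), one-way (1,1) and average-measure (·,k) forms are
  available behind `form`. Confidence bounds are the standard F-based
  intervals (Satterthwaite degrees of freedom for the absolute-agreement
  form); average-measure bounds are Spearman-Brown transforms of the
  single-measure bounds. Negative point estimates are reported as
  computed (category "poor"), never clamped: clamping hides
  variance-structure pathologies. Band boundaries are assigned to the
  band they open (0.5 → moderate, 0.75 → good, 0.9 → good, above 0.9 →
  excellent).
* **Bland-Altman**: bias = mean difference, limits = bias ± 1.96 SD
  (sample SD, n−1). Under normal differences the limits bracket ~95% of
  them; the suite verifies this at n = 100,000. The SVG plot is rendered
  with a fixed hash salt and no date metadata so regenerated reports are
  byte-identical.
* **Cohen kappa on continuous data**: values are binned into fixed-width
  intervals [kw, (k+1)w) anchored at zero, default w = 1.0 cm — about the
  clinically meaningful granularity of an HC chart. Kappa is invariant to
  shifting both series by whole bins; it is sensitive to w, which is
  therefore a visible parameter, not a constant.
* **SEM**: SD·√(1−ICC) — the typical error of a single measurement. The
  literal "standard error of the mean" sd/√n is available behind
  `mode="mean"` because the abbreviation is ambiguous in the reliability
  literature.
* **t / F / Shapiro-Wilk**: pooled two-sample t and the variance-ratio F
  (two-sided, p from the F distribution) are validated by type-I-error
  calibration — 10,000 null replicates must reject within 3 binomial SEs
  of α = 5% — because their textbook formulas leave nothing else to test.
  Shapiro-Wilk delegates to scipy and is restricted to 3 ≤ n ≤ 5000, its
  calibrated range.
* **Survey summaries** round half away from zero to integer percent.

The bundled report (`AgreementStudy.fit()`) pairs the two arms per subject
(averaging repeats within an arm), and runs ICC, Bland-Altman, kappa, SEM,
F, t and Shapiro-Wilk (on the paired differences) in one pass. No
multiple-testing correction is applied; the report is descriptive.

## Problem sizes and tolerances in the test suite

The suite's simulation sizes are chosen so each check is decisive yet the
whole suite stays interactive: ICC parameter recovery uses 100 replicates
of 200-subject studies (Monte-Carlo SE of the mean estimate ≈ 0.001,
against a ±0.05 band); test calibration uses 10,000 replicates (binomial
SE 0.2 percentage points); Bland-Altman coverage uses 100,000 differences
(SE 0.07 points against a ±0.5 band). Pipeline repeatability follows the
30-render protocol of `scripts/acceptance.py`. Geometric exactness
tolerances (10⁻⁶ px on noiseless fits, 10⁻⁵ relative on perimeters) sit
two or more orders of magnitude above double-precision round-off but far
below a hundredth of a pixel — failures indicate algorithmic, not
floating-point, regressions.

## Known limitations

* The oval gate assumes the head is the largest oval object; a large
  circular distractor (bigger than the head) would be selected instead.
* Landmark weighting is a fixed policy, not estimated from data; grossly
  misplaced landmarks will pull the fit wrong with the same force.
* The reference detector is color-based; it needs the stated color to be
  rare in the scene, and a heavily elliptical (tilted) reference fails
  the circularity gate by design rather than degrading silently.
* ICC confidence intervals assume the balanced normal-theory model;
  heavy-tailed measurement errors make them optimistic.
* The kappa binning anchors at zero; measurements straddling a bin edge
  can flip category under sub-millimetre perturbations (an inherent
  property of binning continuous data, visible in the reported bin width).
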