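# Methods

## Measurement model

The package decomposes LV stroke volume (SV) as measured from short-axis (SA)
cine-CMR contour stacks plus long-axis AV-plane landmarks.

**Volumetry.** EDV and ESV are slab sums, `Σ area × spacing`, over the slices
carrying the requested contour (default spacing 8 mm, contiguous slices). No
partial basal-slab correction is applied at the AV plane. The reference SV is
the endocardial volume difference when endocardial contours are present
(clinical convention), otherwise the epicardial difference; for an
incompressible wall the two coincide.

**AVPD.** Six AV-plane landmarks (two per long-axis view: two-chamber,
three-chamber/LVOT, four-chamber) are tracked from ED to ES. Each
displacement is projected on the base→apex long-axis direction (not the
Euclidean distance), so apex-directed systolic motion is positive and
in-plane translation contributes nothing; AVPD is the arithmetic mean of the
six projections.

**Longitudinal contribution.** `V_long = AVPD × A_basal`, where `A_basal` is
the mean ED epicardial area of the two largest slices in the basal half of
the stack (restricting to the basal half keeps mid-ventricular slices of
dilated ventricles out; ties break toward the base; the selected indices are
returned for audit).

**Radial contributions.** Per slice, the ED and ES epicardial contours are
superimposed about a common polar center — the centroid of the ED epicardial
contour — and resampled onto a uniform angular grid (`n_theta = 720`, 0.5°;
<0.2% area discretization error on smooth contours). The signed swept area in
an angular window is `Σ ½(r_ED² − r_ES²) Δθ`: positive for inward systolic
motion, negative for outward (dyskinetic) motion. The septal window is the
arc between the RV insertion points that faces the RV; the lateral window is
its exact complement, so the two partition the swept area by construction.
Slices without their own insertion landmarks (typically apical, where the RV
is no longer visible) inherit the window of the nearest annotated slice.
Swept areas times spacing are summed base→apex; slices lacking an ES contour
(basal planes traversed by the AV plane in systole) contribute zero.

**Internal validation.** `pct_long + pct_sep + pct_lat`, each percentage
referenced to the volumetric SV; 100% in theory.

Contours are closed planar polygons in mm; orientation is normalized to
counter-clockwise on ingest, consecutive duplicate vertices are dropped, and
contours must be star-shaped about the chosen center — a violation raises an
error naming the offending angle rather than silently corrupting signed
areas. Angles are radians, counter-clockwise, 0 along +x; windows are
half-open `[start, end)`.

## Phantom

The synthetic generator emulates the contour data of one subject with fully
prescribed kinematics, so every pipeline quantity has an analytic
counterpart.

*Geometry.* The ED epicardium is a truncated prolate ellipsoid: apex at
z = 0, base plane at z = L (`long_axis_length`), half-axis `c =
L / (2·truncation_fraction)` (default fraction 0.5 → hemi-ellipsoid, base at
the equator), basal radius `base_epi_radius`. The ED endocardium is offset
inward by a uniform `wall_thickness`.

*Systole (piston pump, epicardium-led).* The AV plane translates apically by
`avpd`; below the new base plane the epicardial radius shrinks by a
sector-dependent fraction: `radial_shortening_septal` inside the septal
window (default 120° centered on the septum; negative values prescribe
dyskinesia) and `radial_shortening_lateral` elsewhere, blended across each
sector edge by a 10° cosine ramp so contours stay smooth and star-shaped.
Slices above the ES base plane carry no ES contour.

*Endocardium at ES and wall conservation.* The ES cavity is the scaled ES
epicardial shape with a basal taper closing smoothly (zero area-slope) toward
the mitral annulus over a shoulder of 13% of the long axis (~12 mm); the
scale factor is solved so that total wall volume is exactly conserved between
frames, hence epicardial and endocardial SV agree by construction. The taper
is both physiological — the ES cavity funnels into the closed annulus rather
than ending in a wide flat cut — and numerically important: it makes the
slab-summed ESV (and so the reference SV) accurate for any AVPD, not only
when the AV plane lands on a slab boundary.

*Landmarks and noise.* Six AV landmark pairs sit on the basal ring with the
prescribed displacement, so AVPD is recovered exactly (to float rounding) by
the pipeline. RV insertion points are placed on slices whose epicardial
radius exceeds 40% of the basal radius. When `noise_sd > 0`, independent
Gaussian radial noise is added per contour vertex, reproducibly from `seed`;
noiseless output is seed-independent and byte-identical across runs.

*Analytic ground truth.* `V_long_true` is the integral of the ED epicardial
area over the swept slab `[L−AVPD, L]`; the septal/lateral truths are sector
integrals of `½ r_ED²(1−(1−s(θ))²)` below the slab (quadrature of the same
blended shortening profile). The three sum to the epicardial (= endocardial)
SV exactly, continuously — independent of slice and angular discretization.

*Presets and cohort sampling.* Group presets (control, LAD-MI, RCA-MI) are
calibrated to published group means of a chronic-infarct study: AVPD
(15.4 / 11.0 / 13.0 mm), basal epicardial area (40.2 / 49.7 / 44.5 cm²), EDV
(163 / 277 / 202 mL) and SV (97 / 91 / 98 mL) are pinned per group; wall
thickness is solved from EDV; and the radial remainder `SV − AVPD×area` is
split between septum and lateral wall in the published ratio (9.5:29.2,
5.1:43.5, 9.9:34.7). Because the published per-group percentages sum to
103–107% while the phantom is internally consistent (components sum to SV
exactly), the phantom's true percentages sit a few points below the published
ones; the group *pattern* — reduced septal and raised lateral contribution in
LAD-MI, preserved longitudinal fraction despite reduced AVPD — is preserved.
Long-axis lengths (90 / 105 / 95 mm) are a package choice giving
physiological wall thickness (~5.5 mm control, thinner in the dilated LAD
group). Cohort sampling draws spec fields per subject from independent
normals truncated at ±3 SD, with SD = SE·√n from the published group
statistics (n = 20/16/20); area- and percentage-scale spreads are mapped to
radius/shortening spreads through the analytic sensitivities of the model.
Covariances between fields (e.g. AVPD vs dilation) are unknown and not
modeled.

## Statistics

Group summaries are mean ± SE (SD/√n). Three-group comparisons use classical
equal-variance one-way ANOVA with Tukey–Kramer post-hoc pairwise p-values
(studentized-range distribution; handles the unequal group sizes); two-sample
comparisons use the pooled-variance unpaired t-test. Spearman correlation
uses average ranks for ties; its p-value is the exact permutation probability
for n ≤ 10 (full enumeration) and the classical t approximation above. As is
conventional in this literature, the rank correlation is reported alongside
an ordinary least-squares line fitted to the raw values — two separate
statistics, not one model. Observer variability is bias ± SD of paired
differences.

## Numerical choices and validity domain

- `n_theta = 720` (0.5°); the annular swept-area rule and exact ray–edge
  intersections keep sector areas within 1% of a 0.1 mm rasterization oracle.
- Slab summation quantizes the *epicardial* ES stack at the basal end:
  because ES contours vanish above the AV plane, the epicardial stack SV
  deviates from truth by ≈ `(m·spacing − AVPD)·A_basal`, where m is the
  number of ED-only basal slices. The identity "piston + radial = epicardial
  EDV − ESV" therefore holds (≤2%) when the ES base lands near a slab
  boundary, and the tests verify both the aligned identity and the predicted
  misaligned deviation. The *endocardial* reference SV does not suffer from
  this (tapered ES cavity), so the percentage contributions are stable in
  AVPD: across AVPD 0–20 mm and shortenings −0.1–0.2 (varied about the
  control preset), the pipeline tracks the analytic truth within 3 points
  (longitudinal) and 2 points (septal, varied one parameter at a time; at
  joint extremes with SV ≈ 35 mL the septal deviation can reach ~3 points).
- With 1 mm contour noise, the mean contribution over 50 seeds stays within
  2 points of the noiseless value; no smoothing is applied — noise handling
  is the caller's concern.
- Degenerate inputs fail loudly: fewer than 3 distinct vertices, zero-area
  polygons, non-star-shaped contours, mismatched polar grids, ESV > EDV,
  incomplete landmark sets, and specs whose kinematics leave no ES cavity.

## What the phantom does and does not show

Passing tests demonstrate that the measurement chain recovers prescribed
kinematics from idealized contour data: circular/elliptical sections, a
straight long axis, a flat AV plane perpendicular to the stack, uniform wall
thickness, piecewise-constant sector kinematics and white vertex noise. Real
ventricles have oblique saddle-shaped annuli, papillary muscles and
trabeculation, regionally varying wall thickness, through-plane motion and
spatially correlated segmentation error; accuracy on patient data is a
clinical-validation question the phantom cannot answer. Image-domain effects
(pixelation, partial volume) and RV function are out of scope.
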