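# Methods

`octafaz` quantifies en-face OCT-angiography (OCTA) images of the macula in
diabetic macular oedema (DME) and compares anti-VEGF treatment responders
with non-responders. This note records the models and procedures the
package implements, the parameters that matter, and the choices made where
the design was genuinely open.

## Image model and phantom generator

An en-face angiogram is modelled as an 8-bit grayscale grid with an
isotropic physical scale (default: a 6 mm × 6 mm field sampled at
420 × 420 px, i.e. ≈14.3 µm/px). Flow is bright; the foveal avascular
zone (FAZ) is a dark, texture-free region at the centre.

The phantom generator (`octafaz.synthetic`) emulates exactly this
appearance:

- **Vasculature** — random-walk centrelines (step 4 px, Gaussian heading
  drift of 18°/step) stamped as flat-capped strokes of mean width 2 px
  (capillaries at this sampling bloom to roughly that width), drawn until a
  target areal fraction (default 0.45) is covered. Each stroke starts at
  the least-covered of eight candidate positions, which keeps the mesh
  homogeneous the way a perifoveal capillary plexus is. When rendering a
  full phantom, any residual avascular gap larger than `max_gap_px`
  (default 400 px ≈ 0.08 mm²) is additionally filled: in real OCTA every
  avascular gap other than the FAZ is far smaller than the FAZ, and the
  false-positive-removal stage of segmentation relies on that property.
- **FAZ** — a disk, an ellipse, or a "blob" whose boundary is a radial
  Fourier perturbation (modes 2–5) of a circle with controllable amplitude,
  rasterised exactly; the rasterised mask *is* the ground truth, so
  recovery can be scored without annotation error.
- **Intensities** — background 100, vessels 200, FAZ 30 (contrast well
  above the 60-level floor that keeps the region detectable), plus
  additive Gaussian noise (default SD 8 gray levels; validation sweeps up
  to 20).

Everything is driven by one integer seed; equal seeds give bit-identical
images and tables.

What the phantoms deliberately do **not** emulate: OCT speckle statistics,
projection and motion artifacts, signal-strength falloff, capillary
dropout lesions, or the layered geometry of the two plexuses. Passing the
recovery tests therefore demonstrates correctness of the algorithms under
controlled conditions, not clinical-grade robustness on patient images.

Synthetic cohorts draw one row per eye: demographics, baseline central
subfield thickness (CST), a planted fractional CST change per group
(responders N(0.40, 0.12), non-responders N(0.05, 0.10)), and per-eye OCTA
metrics with per-group means/SDs taken from the published responder /
non-responder contrasts (e.g. outer-ring vessel density 15.5 ± 2.2 vs
14.55 ± 3.57). Setting both groups' parameters equal yields null cohorts
for calibration studies.

## FAZ segmentation

The pipeline localises the FAZ by elimination (all steps deterministic):

1. crop any header band; cut a square ROI (default half-width 100 px)
   around the image centre;
2. Gaussian pre-smoothing (σ = 1.5 px) — without it, noise above ~SD 15
   floods the edge map inside the FAZ;
3. Prewitt gradient magnitude, thresholded at 0.10 × its maximum;
4. morphological closing of the edge map with 5-px line elements at 0°,
   45° and 90° (union over orientations) — fuses vascular edge fragments
   while preserving the FAZ outline; 135° is available by configuration;
5. disk closure (radius 5 px) of the vascular mask — erases
   inter-capillary gaps so that only genuine avascular regions survive in
   the complement;
6. the complement's components are candidate avascular zones: a small
   disk closing (radius 1 px), deletion of components under
   `min_region_px` (80 px), then selection of the largest component.
   Equal-sized candidates are broken by lexicographically smallest
   (row, col) centroid — deterministic and orientation-free. If nothing
   survives, a `SegmentationError` signals segmentation failure rather
   than returning a spurious region;
7. hole filling, then a boundary-compensation dilation of 4 px: the
   thresholded edge band straddles the true intensity step by about
   σ·√(2·ln(1/threshold)) + 1 ≈ 4 px, so the selected region is
   systematically that much inside the boundary;
8. re-embedding in full-field coordinates; the outline is the
   Moore-neighbour-traced boundary of the filled region.

Erosion treats pixels beyond the frame as foreground (the scikit-image
convention), so each per-orientation closing is extensive on the finite
grid.

Measured on a 3 × 3 × 3 grid of FAZ sizes (0.11, 0.31, 1.03 mm²) × noise
SD (5, 10, 20) × seeds, the pipeline reaches median Dice 0.98 with median
absolute area bias under 3%; the worst cell (smallest FAZ at the highest
noise) stays above Dice 0.65. On vessel-only images (no FAZ) it raises a
segmentation failure in ~90% of seeds and otherwise returns regions below
0.06 mm², under half the smallest clinically plausible FAZ.

## Geometric FAZ parameters

Twelve descriptors, in physical units (mm / mm²; tabular exports convert
linear measures to µm):

- **area** — pixel count × scale²; **equivalent diameter** — 2√(A/π).
- **major/minor axis, orientation, eccentricity** — from the ellipse with
  the same second central moments as the region (axis length =
  4√eigenvalue); orientation is CCW-positive from the horizontal axis in
  (−90°, 90°]; eccentricity is the standard dimensionless √(1−(b/a)²),
  zero for a circle.
- **perimeter** — the traced 8-connected contour with weights 1 (axial)
  and √2 (diagonal). This staircase estimator is the stated convention for
  the exported perimeter, but it overestimates smooth boundaries by ~5%
  (measured 4.9–5.3% on digital circles, the classical Freeman-chain
  bias). Because the circularity index is quadratically sensitive to
  perimeter bias (it would read ~0.91 on a perfect disk), circularity is
  computed from the 4-direction Crofton perimeter instead, which is
  unbiased to within ~0.5% on disks of radius ≥ 20 px. Both estimators are
  available from `perimeter_length(..., method=...)`.
- **circularity** — the isoperimetric quotient 4πA/P² (circle → 1,
  square → π/4); digitisation can push it slightly above 1.
- **Fmin/Fmax** — minimal and maximal caliper (Feret) widths of the convex
  hull of the foreground pixel corners, swept at 0.5° granularity.
- **inscribed circle radius** — maximum of the Euclidean distance
  transform; **circumcircle radius** — exact minimal enclosing circle of
  the hull corners.

All of these are cross-checked against independent brute-force oracles
(set-definition morphology, pair/triple enumeration for the enclosing
circle, exhaustive centre search for the inscribed circle, 0.1° caliper
sweeps) on large samples of random masks.

## Vascular parameters

- **Binarisation** — global Otsu by default; fixed thresholds available.
  Foreground is strictly above the threshold.
- **Skeleton** — topology-preserving thinning; weighted length counts each
  8-adjacency as 1 or √2, split half-half between its endpoints so length
  integrates over arbitrary subregions.
- **Vessel diameter index (VDI)** — binarised vessel area / skeleton
  length: the mean vessel calibre, reported in px and mm.
- **Vessel (avascular) density** — vessel pixels / total pixels ∈ [0, 1].
- **Tortuosity** — skeleton branches are split at junction pixels (≥3
  neighbours); branches under 5 px are discarded as thinning spurs. Per
  branch: (arc length / chord length) × (1 + number of curvature
  inflections), averaged over branches weighted by arc length. A straight
  segment scores exactly 1, a uniform arc its arc/chord ratio, and each
  genuine bend reversal adds one multiplicative step. Inflections are
  counted with hysteresis: signed turn angles along a smoothed copy of the
  path (window 7) are themselves smoothed and accumulated per curvature
  sign; a reversal registers only when opposite-sign turning accumulates
  0.3 rad. Staircase raster noise alternates sign step-to-step and never
  accumulates, which is what makes straight diagonals score exactly 1.
  The exact published formulation of tortuosity this emulates is not fully
  specified in the literature it follows, so the formula version is
  recorded in the `VesselStats.tortuosity_formula` field.

## ETDRS densities

The standard ETDRS grid (1 / 3 / 6-mm ring diameters) is rasterised from
the image centre: subfield 1 is the central 0.5-mm-radius disk, subfields
2–5 the inner annulus quadrants, 6–9 the outer annulus quadrants, split by
the 45° diagonals. Quadrant naming follows a laterality convention
(OD: temporal = image left; OS mirrored); the convention renames quadrants
but never changes ring values.

- **Perfusion density (PD)** — percent of a subfield's area covered by
  binarised vessels.
- **Vessel density (VD)** — skeleton length per unit area (mm/mm²). The
  length-based definition is used because its magnitudes (~15 mm⁻¹)
  match the values commercial angiography reports print alongside PD
  (~37%), whereas an area-proportion reading would duplicate PD.
- **Rings** — central {1}, inner {2–5}, outer {6–9}, full {1–9}; ring
  values are unweighted means of the member subfields (the ring
  definitions are stated as means of subfield values, so no area
  weighting is applied).

## Cohort statistics

- **Inclusion** — OCTA signal strength ≥ 7 (configurable).
- **Response readout** — fractional CST change (x − y)/x for baseline x
  and post-treatment y.
- **Stratification** — eyes ranked by CST change, largest reduction
  first; the top two quartiles (first ⌊n/2⌋ records) are responders. With
  an odd n the median-ranked eye goes to the non-responders, which is the
  rule that produces the 30/31 split of a 61-eye cohort. Ties are broken
  by record order, making the split deterministic.
- **Comparisons** — two-sided pooled-variance Student t-test for
  continuous variables (Welch by flag), Pearson χ² without continuity
  correction for categorical counts. The Bonferroni threshold is α/m with
  m equal to the number of comparisons actually run, not a hard-coded
  constant, because the published per-family m is ambiguous (twelve
  comparisons are described alongside a 0.002 ≈ 0.05/24 threshold).
- **Contribution table** — per significant variable: mean difference
  (responder − non-responder) and percentage change
  (non-responder − responder)/responder × 100, rounded to 2 decimals;
  status is *Decreased* for negative change, *Increased* otherwise.

Calibration: over ≥ 2000 null cohorts of n = 30/31 the empirical type-I
error of the pooled t-test at α = 0.05 must lie in [0.04, 0.06], and the
empirical power for a 1-SD planted effect tracks the closed-form
noncentral-t power within 5 points. Both checks run in the test suite.

## Problem sizes used in validation

The test suite and the acceptance script use: disks of radius 20–100 px
for geometric recovery; a 3 × 3 phantom grid (FAZ 0.11–1.03 mm² × noise
SD 5–20) for segmentation recovery; 1000 random 16 × 16 masks for the
brute-force oracle comparisons; 2000–5000 null cohorts for t-test
calibration; and 4–12-eye cohorts for end-to-end runs. These sizes give
stable estimates (e.g. ±0.3 pp Monte-Carlo error on the type-I rate at
5000 simulations) while keeping a full run in a few minutes.

## Known limitations

- The ROI is centred on the image; there is no foveal re-centration for
  poorly centred scans.
- Largest-component selection assumes the FAZ dominates all other
  avascular gaps; severe capillary dropout adjacent to the fovea could
  defeat it (and the no-FAZ failure mode shows the flag works).
- The SCP/DCP slab projection itself is out of scope: the package consumes
  already-projected en-face images.
- Patient-level published tables (means, SDs, p-values) are not
  reproducible without the original images and records; the package
  reproduces the published table arithmetic and validates every stage
  against synthetic ground truth instead.
- The eccentricity and VDI scales printed in the source tables are
  internally inconsistent (eccentricity ≫ 1 "mm", VDI ~28 "mm"); the
  package reports standard dimensionless eccentricity and labels VDI in
  px and mm without asserting correspondence to those printed scales.
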