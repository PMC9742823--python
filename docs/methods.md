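# Methods

## The measurement model

The quantity estimated is the projected (camera-facing) rosette area of
*Arabidopsis* seedlings grown in a row near the top of a closed, square
agar plate. The estimate is a pixel count under a binary leaf/non-leaf
classification, multiplied by a physical scale factor:

    area_mm2 = pixel_count × mm2_per_px

Both factors are measured from the image itself, so the method assumes:
the plate is the dominant high-contrast rectangle in the frame; leaf tissue
is separable from plate and background on a single color channel; rosettes
do not overlap across seedling positions (overlaps are flagged, not
resolved); and the scale object (red marker or plate) is roughly coplanar
with the rosettes, so one global mm²/px factor applies.

## Plate detection and rotation

Two interchangeable strategies produce a candidate binary map: global
thresholding of the grayscale image (light or dark plate), or canny edge
detection. The map is cleaned by morphological closing (disk radius 5 px)
and hole filling; connected regions are kept if they cover at least
`min_area_fraction` (default 0.2) of the frame with a bounding-box aspect
in [0.5, 2.0], and the largest survivor is the plate. A second candidate
within 1% of the winner's area raises an ambiguity error rather than a
silent guess.

The plate's tilt is the angle of its minimum-area rotated rectangle
(convex hull + rotating-calipers), normalized into (−45°, +45°] to resolve
the 90° ambiguity of a near-square outline, ties toward the smaller
magnitude. Coordinates are 0-based, origin top-left, rectangles half-open.

**Tilt handling without resampling.** Rotating pixels (any interpolation
order) perturbs the area of ~100-px objects by several percent — more than
the measurement error budget. The pipeline therefore never resamples for
measurement: segmentation runs on the un-resampled axis-aligned crop of the
plate contour, and the de-rotation is applied to object *coordinates* only,
for the ROI test and slot clustering. Pixel counts are exact native-raster
counts at any tilt. `crop_to_plate` still provides a resampled de-rotated
crop (bilinear by default, nearest-neighbor optional) for display and
debug output.

## Leaf segmentation

Channel extraction supports the naive device CMYK transform
(K = 1 − max(R′,G′,B′); C = (1 − R′ − K)/(1 − K), defined 0 at K = 1 —
fixed formula for bit-reproducibility, no ICC profile) and the standard
sRGB → XYZ(D65) → CIELAB transform with a\*/b\* shifted so 128 is neutral.
Green tissue is bright in CMYK-C and dark in Lab-b; the threshold direction
is explicit configuration, never inferred. Otsu's method
(between-class-variance maximization) is the default threshold; a 256-bin
histogram helper supports manual threshold choice for a new image set, with
optional histogram equalization for low-contrast sets.

Objects are 8-connected components. The region of interest keeps the top
`top_fraction` (default 0.5) of the plate crop minus a 2% side margin:
rosettes that have fallen below the plate midline are excluded by design
and reported in the unmeasured tally. Components are clipped to the ROI
first, then components smaller than `min_object_px` (default 25 px at
~0.8–2 MP) are discarded as speckle.

Shoot grouping is deterministic 1-D k-means on centroid *x* (k = min(6,
#objects), centers initialized at evenly spaced quantiles, pixel-count
weighted), each cluster then assigned to the nearest of six equal-width
columns. Fragments of one rosette merge within a column; two clusters
claiming one column raise a `slot_collision` flag (overlapping seedlings —
both merged, measurement marked unreliable). A shoot's pixel count is the
zeroth image moment of its merged mask, which equals the boolean pixel sum
exactly.

## Scale calibration

`mm2_per_px = known_physical_area / measured_pixel_count`, from either the
largest red component (a\* channel thresholded at 158, the midpoint between
the neutral and strong-red modes, so edge pixels split evenly) in a search
region below the shoot ROI, or the detected plate's enclosed pixel area
against its configured physical dimensions (default 100 × 100 mm). Marker
wins when both are configured; falling back to the plate sets a
`scale_fallback` flag. Plate-as-scale uses enclosed *area*, not side
length, because area is what detection measures robustly under slight
rotation. Neither marker size nor plate size has a privileged default —
they are image-set properties and required config.

## Statistics

`ols_fit` is the closed-form simple-regression solution (normal equations);
R² = 1 − SS_res/SS_tot. `anova_h2` fits a sequential (type-I)
fixed-effects model, genotype first, then nitrogen source, then nitrogen
treatment — the source × concentration combination, entered as the
concentration-within-source contrast so the design stays full-rank while
its sequential SS equals treatment-after-source. Broad-sense heritability
is defined as the genotype share of the total sum of squares,
H² = SS_G/SS_total — deliberately the sum-of-squares definition, not a
REML variance component. Unbalanced tables (failed germination) enter
as-is; type II is available. An all-constant response returns H² = 0 with
a degeneracy flag.

## The synthetic-image generator

Scenes emulate the salient features of closed-plate photography: a light
square plate (default 70% of the short image dimension, representing
100 × 100 mm) on a darker background, up to six green rosettes in a row in
the plate's top half, an optional red square marker (nominal 100 mm²)
below them, plate tilt, per-channel additive Gaussian sensor noise clipped
to [0, 255], and a linear lateral lighting ramp. An inverse-contrast
variant (dark plate, light background) exercises the dark-object and edge
detection paths. Rosettes are unions of 3–7 elliptical lobes (disk and
square shapes exist for exact-geometry tests); default sizes are drawn
uniformly from 5–40 mm², the plausible range for 12-day seedlings.
Batches default to 1024 × 768 px, 50 plates, tilt uniform in ±10°, noise
SD 4, germination probability 0.92.

Ground truth is counted from the rendered raster, never from analytic
geometry, and anti-aliasing is disabled, so truth and image cannot
disagree. After rasterization each blob's boundary is deterministically
adjusted (add concavity-filling pixels / remove tip pixels, preserving
8-connectivity) until it holds exactly its target pixel area; the rotated
marker gets the same treatment. This makes rotation- and
resolution-invariance of the measurement testable at tight tolerance.
The generator does **not** model roots, condensation, plate labels,
perspective, lens distortion or photorealistic texture — passing tests
demonstrate correctness of the measurement logic under controlled
conditions, not segmentation robustness on arbitrary real photographs,
where channel/threshold choices must be tuned per image set.

The factorial-area simulator draws additive genotype, treatment and
residual effects. A factor's "variance fraction" is defined as its expected
share of the total ANOVA sum of squares in the balanced design; effect SDs
are solved jointly from the requested shares (between-group SS absorbs a
(levels−1)·σ²ₑ noise term, so the solve is a 3×3 linear system) and the
drawn effects are standardized to their exact target SDs, so realized SS
shares concentrate tightly even at 100 genotypes × 4 treatments × 2 reps.

## Numerical and design choices

- Determinism everywhere: seeded `default_rng`, quantile-initialized
  k-means, filename-sorted batch order, fixed float formatting in the CSV —
  batch reruns are byte-identical.
- Problem sizes: validation batches are 50 plates at 1024 × 768 px (a
  single 2 MP image processes in ~3 s); unit tests use 400–800 px scenes.
- Failure policy: flag-and-continue in batch mode (`plate_not_found`,
  `scale_fallback`, `slot_collision`, `empty_roi` flags; unreadable files
  become log records), fail-fast in single-image mode.
- Known limitations: slot collisions are flagged, never resolved; only
  square/rectangular plates (no round Petri dishes); one plate per image;
  the CMYK transform is the naive device formula, so thresholds tuned on
  profile-converted imagery will not transfer.
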