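# Methods

## The ATW model

ATW summarizes a false-color class-activation heat map as the foreground
mean of per-pixel temperature weights. The procedure assumes the heat map
uses a jet-style palette in which temperature runs blue → green → yellow →
red; it consumes the rendered image only, not the underlying activation
tensor, so it is agnostic to the network that produced the map.

Pipeline per pixel:

1. **Color space.** sRGB → CIELAB with IEC 61966-2-1 companding, D65
   white, 2° observer. The white point is taken as the image of RGB
   (1,1,1) under the sRGB→XYZ matrix (X_n = 0.950456, Y_n = 1.000000,
   Z_n = 1.088830 to 6 dp), which makes L*(white) = 100 exact up to
   floating-point rounding. Lab is used because Euclidean-ish color
   comparisons there track perception far better than in RGB.
2. **Family assignment.** CIEDE2000 distance to each of four anchors.
   The nearest anchor's family wins; distances equal within 1e-9 go to the
   hotter family (deterministic tie-break; ties occur only on a measure-zero
   boundary set).
3. **Weight interpolation.** For family *f* with band [lo, hi] and
   next-cooler anchor *g*: `w = hi − (hi − lo)·d_f/(d_f + d_g)`, clamped to
   the band. The blend is continuous inside a family, equals `hi` exactly at
   the anchor (d_f = 0), and approaches the band midpoint-complement at the
   decision boundary (d_f = d_g ⇒ w = (hi+lo)/2 offset, e.g. 0.9 on the
   red/yellow boundary). Blue is identically 0 — it has a point weight, not
   a band — so the green/blue decision boundary carries a jump from ≈0.5 to
   0. That discontinuity is inherent to assigning the coldest family zero
   weight and is accepted.
4. **Averaging.** Mean over the foreground mask; undefined (error) for an
   empty mask.

### Anchors

The reference hues are not prescribed anywhere beyond their names, so the
package uses the pure display primaries red (255,0,0), yellow (255,255,0),
green (0,255,0), blue (0,0,255) — the extremes of the common jet palette —
and makes them overridable via a YAML scheme file. Because real Grad-CAM
renderings depend on the plotting library's colormap, absolute ATW values
are scheme-dependent; comparisons between two maps scored with the same
scheme are the meaningful quantity.

### Segmentation

Background suppression ("leave only the thermally active foreground") is a
stated preprocessing step without a stated rule, so three strategies are
offered and none is claimed canonical:

* `full` (default) — identity mask; makes scores reproducible from the
  image alone;
* `external` — caller-supplied binary mask (e.g. from a detector's boxes);
* `anchor_proximity` — keep pixels within τ ΔE00 (default 30) of any
  anchor. This removes photographic background blended into overlay
  renderings; on synthetic overlays at α = 0.85 it recovers ≥ 80 % of the
  true heat region (frozen regression floor in the test suite).

## Detection evaluation

* IoU on normalized center-format boxes; greedy matcher in descending
  confidence (stable for equal confidences), each detection taking the
  unmatched same-class ground truth of maximal IoU ≥ 0.5, IoU ties to the
  lower ground-truth index. Greedy confidence-ordered matching is the
  convention of the YOLO-family evaluation stacks; an independent
  plain-python restatement of the rule serves as the oracle in tests.
* AP uses all-point interpolation (monotone precision envelope integrated
  over recall), the modern PASCAL/COCO-style choice; the legacy 11-point
  variant is available by argument. mAP50 is the mean over classes present
  in the ground truth and reduces to AP50 for single-class data.
* Field accounting reports detected = (n_gt − FN) + FP and rates FN/n_gt,
  FP/n_gt as percentages rounded **half-up** to one decimal, matching how
  such tables are conventionally printed (11.398 → 11.4).

## Dataset tooling

* **Split rule.** For ratios (0.8, 0.1, 0.1): `val = round(0.1·N)`
  (half-up), `test = floor(0.1·N)`, `train = N − val − test`. This is the
  unique simple rounding scheme consistent with the published sizes
  2687/336/335 at N = 3358 (plain rounding of all three parts gives
  336/336 for val/test and a different train count). Assignment is a seeded
  uniform permutation.
* **Affine.** Rotation/scale about the continuous image center plus
  translation; boxes are remapped as the axis-aligned hull of their four
  transformed corners (the standard convention — it over-covers rotated
  content slightly), clipped to the canvas, and dropped below a minimal
  normalized area (1e-4).
* **Cutout** fills mean-color rectangles and leaves labels untouched
  (occlusion-robustness semantics); an optional threshold drops boxes ≥ 80 %
  occluded.
* **Mosaic** composes four images about a jittered center; remapped boxes
  are dropped when the clipped side falls under 2 px or the clipped area
  under 1 % of the pre-clip box.
* **Environment presets** are parameter bundles over the photometric ops:
  `direct_sun` (+brightness, +saturation), `dim` (−brightness,
  −saturation), `fog` (contrast 0.45 + haze lift), `noise` (Gaussian
  σ = 0.06 on the unit intensity scale).
* All operators are pure and bit-reproducible for a fixed seed
  (`numpy.random.default_rng`).

## Synthetic fixtures

Real heat maps and field logs are not bundled; fixtures are generated:

* Activation fields are clamped sums of isotropic Gaussians rendered
  through a piecewise-linear jet-like colormap whose breakpoints (0, 1/3,
  2/3, 1) hit the four anchors exactly, so family assignment at
  breakpoints is analytic.
* The ATW oracle re-walks the whole chain per pixel in a deliberately
  naive double loop and must agree with the vectorised metric to 1e-9.
* Detection scenarios place ground truths in distinct cells of a regular
  grid (box side 0.4 of the cell ⇒ distinct ground truths have IoU 0),
  jitter the emitted detections by at most 15 % of the box side (IoU with
  the parent stays ≥ 0.68 > 0.5), and center false detections in unused
  cells. The matcher therefore provably recovers the requested
  (TP, FP, FN), which is what makes the field-accounting reproduction an
  end-to-end computation rather than arithmetic on constants.
* The overlay background is a seeded greenish noise texture — a synthetic
  stand-in for a field photograph. Fixtures exercise colorimetric and
  matching logic fully, but contain no real foliage textures, camera noise,
  JPEG artefacts or colormap variants, so green tests bound correctness of
  the computation, not detector performance on real imagery.

## Model arithmetic

* GhostConv ratios: exact forms
  `r_s = c·k² / (c·k²/s + ((s−1)/s)·d²)` and
  `r_c = n·c·k² / ((n/s)·c·k² + (s−1)·(n/s)·d²)`; the spatial factors
  cancel, both ratios coincide after simplification, and both → s as
  c → ∞ with d ≈ k. Exact and asymptotic values are reported separately so
  approximation quality stays visible.
* Cosine annealing: `η_t = η_min + ½(η_max − η_min)(1 + cos(π t/T_max))`,
  0-based round index, evaluated per epoch. Default η_max = 0.007 (the
  study's initial rate) and T_max = 300; η_min has no published default
  and must be chosen by the user (0.0 if unset).

## Problem sizes and numerics

The test suite and acceptance script use 16×16–48×48 heat maps,
25–100 random fixtures per property, 930-target field scenarios, and the
full 3358-item split — sizes at which every check runs in seconds on one
CPU while still exercising each code path and branch (including the
CIEDE2000 hue-discontinuity cases via the 34 published verification
pairs). Tolerances: 1e-4 against published color-difference values
(their printed precision), 1e-9 for oracle-vs-implementation equivalence,
1e-12 for algebraic identities.

## Known limitations

* Absolute ATW values depend on the anchor scheme and the segmentation
  strategy; published per-image ATW figures from any specific study are not
  reproducible without that study's rendered heat maps.
* The greedy matcher is the conventional, not the optimal-assignment,
  matcher; with the non-overlapping fixture geometry the two coincide.
* Augmentation rasters use bilinear interpolation; sub-pixel differences
  across BLAS/platform builds are possible in warped images, though box
  coordinates are computed in closed form and exact.
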