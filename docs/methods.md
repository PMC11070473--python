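# Methods

## Measurement model

The stem is treated locally as a convex solid of revolution; what the
camera sees of it at one image row is the silhouette chord between the two
tangent rays. The measurement reconstructs that chord in 3-D:

* the two contour intersections of a horizontal scanline are the tangent
  pixels,
* a shared depth `d` places them in space via the pinhole back-projection
  `Z = d`, `X = (x−c_x)/f_x·Z`, `Y = (y−c_y)/f_y·Z`,
* the Euclidean distance of the pair, after the y/z axis inversion into
  the color-stream frame and the rigid color→depth mapping, is the
  diameter in mm. Both mappings are isometries, so the number is
  frame-independent; the pipeline asserts this per measurement at
  1e-9 mm.

All lenses are modeled as undistorted pinholes. Pixels are 0-based
`(col, row)` with the pixel center at integer coordinates. Depth rasters
are 16-bit integers at `depth_scale` meters per unit (default 1 mm), 0 =
invalid. Every 3-D point carries a frame tag (`opencv`, `color`, `depth`)
and the transforms check tags, because the three-frame choreography is the
easiest place for silent sign errors.

### Choice of the shared back-projection depth

The silhouette tangent points of a cylinder of radius R viewed from
distance D sit at essentially the axis depth, while the stem surface at
the centerline (where the skeleton point is) is nearer by R/sin a, with a
the ray-to-axis angle. Feeding that front-surface depth to both edge
pixels therefore underestimates the diameter by about `R/(D sin a)` —
2–4 % in the working range (R up to 20 mm, D 0.45–0.9 m, a 45–70°).

The default rule (`depth_source="edge"`) estimates the tangent depth as
the mean of the depths read at the two edge pixels themselves, each
accepted only within 40 mm of the center depth. The gate bounds the
largest plausible tangent-to-front offset (√2 × 22 mm ≈ 31 mm) plus
sensor noise, and rejects background bleed-through at the silhouette
boundary; when neither edge depth survives, the center depth is the
fallback. The two edges deliberately share one depth: with per-edge
depths, an asymmetric fallback injects a spurious depth difference
between the endpoints that inflates the 3-D chord in quadrature (observed
up to +14 % on synthetic scenes). A pure center-depth mode
(`depth_source="center"`) is retained; it satisfies the closed-form
identity `diameter = width_px · Z_center/f` exactly and is useful for
analysis, at the cost of the systematic underestimate above.

Edge pixels are back-projected at their outer half-pixel coordinates
(`left−0.5`, `right+0.5`): each contour pixel covers a unit footprint and
the stem boundary runs along its outer edge. Using pixel centers instead
discards one full pixel of width — about 1 mm (4 %) at 0.6 m with
f ≈ 615 px.

Each depth lookup falls back to the median of valid values in a 5×5
window when the exact pixel is invalid; the aligned raster is sparse by
construction (nearest-pixel z-buffer splatting, no hole filling, so
unfilled pixels stay visibly empty rather than being interpolated).

## Segmentation

HSV gating plus Otsu: hue in 35°–85° selects green vegetation; Otsu's
threshold on the 8-bit saturation histogram *inside the gate* separates
saturated stem tissue from dull soil-colored pixels that slip through the
hue gate. Otsu always returns an argmax, even on a unimodal histogram
where the split would only bisect sensor noise, so the split is accepted
only when its separability η = σ²_between/σ²_total reaches 0.75; below
that the whole gate is kept. (A unimodal Gaussian tops out at η ≈ 0.64;
well-separated bimodal histograms exceed 0.9.) The threshold operation
itself is exhaustive over the 256 levels with smallest-level tie-break.

Cleaning uses a 5×5 median (strict majority), opening with a 3×3
elliptical element, and largest 8-connected component; the contour is the
internal gradient with the same 3×3 element. All local filters use
reflection padding so the image border is not artificially eroded. These
kernel choices are the smallest that remove speckle without eroding a
≥15 px stem; they are parameters, not constants.

## Skeletonization

Classical two-subiteration thinning with simultaneous deletion within each
sub-step (conditions evaluated on the sub-step's input), iterated to a
fixed point. Neighbor order is clockwise from north; sub-step A deletes
when `2 ≤ N ≤ 6`, `S = 1`, `N·E·S = 0`, `E·S·W = 0`, sub-step B with the
west/north symmetric conditions. Consequences verified by tests: the
skeleton is a subset of the mask, the operation is idempotent, component
count is preserved on the fixture masks, and on rendered stems the
centerline tracks the true projected axis within ~1 px away from the
endpoints. Spur pruning (peeling line terminations, identified by a
single neighbor-run, `min_length` times) exists for field masks with leaf
stubs but is off by default — it also shortens the centerline's free ends.

Scanline rows are chosen evenly across the region of interest, by default
the 0.55–0.80 fractional band of the stem bounding box (the lower-middle
internode region); the ROI is configuration, not detection, because
automatic internode localization is out of scope.

## Evaluation metrics

MAPE, MAE, RMSE as usual; R² is computed against the identity line
(`1 − Σ(k−w)²/Σ(k−k̄)²`), not from a fitted regression, and can be
negative. Lin's CCC uses population (1/n) moments — at n = 60 the
sample-moment variant differs by <5e-4, below the 3-decimal reporting
precision, which a test pins down. The Wilcoxon signed-rank test drops
zero differences, is two-sided, and defaults to the normal approximation
with tie-corrected variance and *no* continuity correction, the variant
that reproduces the packaged tables' reference p-values (0.5005, 0.0736)
to four decimals; the continuity-corrected and exact variants are flags.
Quartiles use linear interpolation (numpy's default) with the convention
exposed, since box-plot conventions differ between tools.

The two packaged tables are 60 paired (method, caliper) diameters for the
depth-based method and for a checkerboard-referenced pinhole-imaging
baseline on the same plants. They are inputs to the metrics suite and
fixtures for its tests; the suite reproduces their published statistics
exactly at printed precision (MAPE 3.01 %/7.34 %, MAE 0.75/1.82 mm, RMSE
1.07/2.22 mm, R² 0.96/0.82, CCC 0.978/0.909, medians 23.74/24.47 vs
23.64 mm).

## Synthetic scenes

The renderer ray-casts a right circular cylinder of known radius against
a farther background plane, analytically per pixel, in both cameras: depth
(nearest-surface Z, optionally quantized to depth units, optional i.i.d.
Gaussian noise) on the depth grid, color on the color grid, plus the exact
silhouette, per-row width, projected axis and surface point cloud. A real
stem is neither perfectly circular nor noise-free in color, and real
stereo depth has correlated speckle and edge dropout rather than i.i.d.
noise — so passing synthetic tests demonstrates geometric correctness of
the pipeline, not field robustness.

The default scene matches the acquisition geometry the method targets:
848×480, stem ~0.6 m away, camera pitched 45° down (so the axis is
strongly inclined out of the image plane but projects near-vertically),
millimeter depth units, ~15 mm color/depth baseline. The 20-scene fixture
suite sweeps diameters 17–41 mm (the field tables' range), distances
0.45–0.9 m, pitches 35–55° and in-image inclinations up to 10°, with
poses assigned from the suite seed. In-image inclination is capped at
10° deliberately: the method's scanlines are horizontal image rows, and a
stem tilted φ *in the image plane* inflates the horizontal chord by
1/cos φ (+15 % at 30°), which is a property of the method, not an
implementation defect; upright field stems stay within a few degrees.
Scene specs reject in-plane inclinations beyond 30°.

End-to-end on this suite the pipeline's MAPE is ~1.6 % noiseless and
~1.6 % with 2 mm depth noise (seed 1; other seeds give 1.1–1.6 %),
computed by `scripts/acceptance.py` — within the 3 % scale the method
achieves on real plants. Residual error is dominated by pixel
quantization on small/far stems (1 px ≈ 8 % of a 17 mm stem at 0.9 m)
and the remaining tangent-depth approximation.

## Numerical and degenerate-input choices

* Alignment re-quantizes Z with the same depth scale and keeps the
  smallest Z per target pixel; ties in Otsu go to the smallest level;
  ties in largest-component go to the component seen first from the
  top-left.
* Empty hue gate, empty point cloud, and empty manifest warn and return
  empty results; empty masks where a component is required raise.
* Scanlines that fail (open contour, no valid depth) are skipped and
  logged in the result; the stem fails only when all scanlines fail.
* Thinning has a max-iteration guard (half the larger image side plus
  two) that raises rather than looping on pathological input.
* Camera configs round-trip bit-exactly through YAML; depth PNGs and PLY
  clouds round-trip losslessly at their declared precision (float32
  vertices, uint8 colors).

## Known limitations

Single dominant stem per frame; no occlusion handling, no leaves or
clutter in the synthetic scenes; no learned segmentation; no distortion
model; ROI is supplied, not detected; the pinhole baseline takes its
mm-per-pixel scale as input rather than detecting checkerboard corners.
The point-cloud annotation assumes the cloud is exported in the viewer's
depth-stream convention (y, z inverted from the pinhole depth frame) with
an essentially rotation-free color/depth baseline, as small-baseline
RGB-D modules have; with a large rotation between streams the annotated
markers and an externally exported cloud would disagree by the
conjugation of that rotation with the axis flip.
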