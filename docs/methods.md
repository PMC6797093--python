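# Methods

This note records the models and procedures the package implements, the
parameters that matter, the design choices made where more than one
reasonable reading existed, and what the synthetic tests do and do not show
about real UAV data.

## Enhancement transforms

**Linear contrast stretch.** The stretch maps stored digital numbers (DN)
to display gray levels so the occupied DN range fills [0, 255], clipping a
fraction `s` of extreme pixels at each end (default `s = 0.01`, the 1%
saturation stretch). Quantiles use linear interpolation between order
statistics, and all 8-bit quantization in the package rounds half away from
zero; both conventions are fixed so results are bit-stable across platforms.
Percentiles are computed per band independently (each band's histogram is
stretched against its own extremes); a joint-quantile mode (`per_band=False`)
is available when a common stretch across bands is wanted. A band whose low
and high quantiles coincide cannot be stretched and is passed through with a
warning rather than raising — a constant band is valid imagery (e.g. padded
margins).

**Synthetic color transform.** The SCT false-colours a single band (the
green band of the mosaic) from its spatial-frequency split. The filter
family is a genuinely open choice; the package commits to a Gaussian
low-pass with the high-pass as the residual, because the pair is linear,
separable-fast, parameterized by one sigma, and sums exactly back to the
input. The default `sigma = 25 px` is roughly one canopy diameter at the
40 m ground resolution (a young plant spans < 50 px), which puts canopy-scale
scattering into the low band. Hue is the min-max normalization of the
low-pass rescaled to [0, 2/3] (red through blue) — restricting the hue range
keeps the two normalization extremes visually distinct, which full-circle
hue would not (0 and 1 are both red). Value is the min-max normalization of
the high-pass; saturation is fixed at 0.5. Min-max normalization makes the
output invariant to a global additive offset of the input, which is the
intended behaviour for a transform that displays *structure*, not level.

**Triangular greenness index.** The broadband form `G − 0.39 R − 0.61 B`
is computed in integer arithmetic as `(100 G − 39 R − 61 B) / 100` so that
gray pixels give exactly zero (the coefficients sum to one; naive float
evaluation leaves ±1e-14 residue). The signed band is quantized to 8 bits
either per-image min-max (default — maximal contrast within one mosaic,
which is what a detector trained per-variant sees) or with the fixed map
[−255, 255] → [0, 255] when values must be comparable across images. Which
of the two a production workflow used upstream is not recoverable from the
output; both are first-class. The narrow-band reflectance form
`−0.5 [190 (R670 − R550) − 120 (R670 − R480)]` is provided as a utility for
calibrated sensors; no radiometric calibration is attempted here.

## Tiling

Tiles are `tile_size = 600` px squares with `overlap = 50` px (stride 550)
for detection regions, overlap 0 for training-style tiling. Grid origins are
`{k·stride}` per axis with `n = ceil(dim / stride)` tiles per axis. This
convention covers every mosaic pixel and reproduces the three documented
region-of-interest tile counts (247, 165, 108) from the corresponding
extents, which is what pins it down; a convention that stops when a tile's
origin passes `dim − tile_size` gives different counts. Edge tiles are
zero-padded to full size rather than shrunk so a detector always receives
fixed-size input; whether a production pipeline padded or clipped cannot be
distinguished from counts alone, and padding is the committed behaviour.
Names encode the origin (`tile_{x}_{y}`, x = column offset first) and the
parser is the single authority for the mapping; coordinates are 0-based,
origin top-left, tile windows half-open.

The 50 px overlap is tied to plant size: a young banana canopy spans less
than 50 px at the 40 m resolution, so every plant lies wholly inside at
least one tile and edge plants are never lost — they are merely detected
twice, which the centroid merge removes.

## Detection

The detector stage is a contract, not a model: anything that emits per-tile
boxes participates. `DetectorConfig` carries the settings an external CNN
detector is expected to run with (IoU threshold 0.5 for its internal
duplicate suppression, at most 300 proposals); these are pass-through
metadata for external backends. The package's own classical reference
detector binarizes an 8-bit TGI tile at `tgi_threshold` (default 200),
labels 4-connected components, keeps those with area in
`[min_area_px, max_area_px]` (defaults 100/4000, bracketing the canopy area
range of the synthetic scenes), and returns tight bounding boxes scored by
mean component intensity / 255. In the pipeline the reference backend
reduces any 3-band variant tile to an 8-bit TGI band first (mosaic-level
min-max, so per-tile normalization does not shift the threshold), which lets
the classical detector run on every variant. Score semantics are advisory:
the fusion stages are purely geometric.

## Centroid fusion

"Merge centroids within a Euclidean distance threshold" is formalized as
single-linkage clustering: clusters are connected components of the graph
with an edge between any two centroids at distance ≤ threshold, found with a
KD-tree pair query and union-find. The cluster representative is the
arithmetic mean of its member centroids. Among the defensible choices
(mean, highest-score member, first point), the mean is symmetric in its
inputs, order-free, and commits to no detector's score calibration. Cluster
means are accumulated over members sorted lexicographically by coordinate,
so the output is bit-identical under permutation of the input. Thresholds
default to 30/25/20 px at 40/50/60 m and 30 px for cross-altitude merging —
values just below the closest plant spacing at each scale. Automatic
threshold selection from observed spacing is deliberately not attempted;
the threshold is study-specific configuration.

Cross-altitude fusion maps each altitude's plant points into the reference
altitude's frame with the per-axis linear transform
`x' = x·s_x + t_x`, `y' = y·s_y + t_y` (scale = ratio of region widths /
heights; shift = observed lateral offset), then merges the pooled points at
the cross-altitude threshold. Only this scale+shift model is supported — no
affine or feature-based registration. A least-squares estimator from ≥ 2
corresponding point pairs is provided as a convenience for deriving the
transform from control points. Coordinates stay real-valued end to end; no
rounding until display.

## Evaluation

Matching of predicted to true plant points is one-to-one within a radius
(default: the reference altitude's merge threshold). The default pairing is
greedy by ascending pair distance — deterministic and auditable; an optimal
assignment-based matcher (Hungarian algorithm on the thresholded distance
matrix) is available as an option and agrees with greedy whenever clusters
of points are isolated, which is the operating regime of a plantation with
spacing well above the match radius. TP = pairs, FP = unmatched predictions,
FN = unmatched truth; precision = TP / detected (defined as 0 with a logged
warning when nothing was detected), recall = TP / ground truth, overall
accuracy = their mean. Metrics are stored unrounded and displayed at three
decimals, rounded half away from zero.

A geometric radius is necessarily an operationalization of a visual
"the box contains one plant" judgment; no radius reproduces a human call
exactly, and the radius is exposed as configuration for that reason.

## Synthetic data

The generator's defaults emulate the study conditions: planting grids at
1.5 m spacing, ground resolutions 1.78/2.03/2.54 cm/px for the 40/50/60 m
altitudes, canopies rendered as filled polar roses
`r(θ) = R(0.55 + 0.45 |cos(kθ/2)|)` with k = 5–8 lobes and radius 10–18 px
(star shape with multiple maxima, spanning < 50×50 px at 40 m), optional
small "sword sucker" blobs touching a plant, integer position jitter of
±4 px, and grass as uniform per-pixel speckle (±8 DN) around a green base.
Canopy and grass colours are chosen so that plant-pixel TGI exceeds
background TGI even at worst-case speckle and jitter — the property that
makes the reference detector exact on noiseless scenes. Altitude variants
are produced by anti-aliased downscaling plus a sub-pixel translation, and
the generator returns the exact inverse transform, so transform round-trip
tests have a known answer.

The detector simulator draws, per plant and per covering tile, a Bernoulli
detection with the variant's probability, Gaussian box-centre noise, box
sides from a configurable range, and Poisson false positives per tile.
Variants use disjoint random substreams, so their errors are independent by
default; a shared-miss correlation parameter (default 0) lets tests stress
how correlated failures erode the multi-variant fusion gain, which with
independence follows the closed form `1 − (1−p)^k` for k variants at
detection probability p.

What the synthetic scenes deliberately omit: shadows, sun-azimuth effects,
leaf overlap between adjacent plants, orthomosaic stitching distortion, and
photorealistic texture. Passing the synthetic suite therefore demonstrates
the correctness of the bookkeeping, fusion and evaluation machinery and the
statistical behaviour of multi-source fusion — not the detection accuracy
any particular trained model would reach on real farms.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (numpy `default_rng`);
identical specs and seeds reproduce images, ground truth and simulated
detections bit-exactly, and pipeline outputs are pure functions of
(inputs, config, seed). The test suite runs its statistical checks at desk
scale by choice: the closed-form fusion check uses 1000 simulated plants on
a 6200×3900 px layout, dominance checks use 200 plants over 8 seeded
replicates, and end-to-end runs use a 9×14-plant rendered farm spanning six
overlap tiles — large enough for binomial tolerances and overlap-band edge
cases, small enough to iterate on quickly.

## Known limitations

* No trained detector ships with the package; real-data accuracy is
  entirely a property of the external detector wired in.
* GeoTIFF georeferencing tags are passed through verbatim on read/write but
  never interpreted; all geometry is pixel-space.
* The scale+shift altitude model cannot absorb rotation or shear between
  mosaics; badly registered inputs need external alignment first.
* The evaluation radius conflates localization error with identity: two
  predictions straddling two adjacent true plants can each match either
  plant when spacing approaches the radius.
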