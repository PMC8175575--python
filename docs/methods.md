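# Methods

## Problem setting

Transverse sections of skeletal muscle are mosaics of polygonal myofiber
cross-sections outlined by membrane/basal-lamina stains (Laminin, WGA) or
filled by cytoskeletal stains (Phalloidin). Instance segmenters deliver
label images — integer rasters, 0 for background, one positive ID per
fiber. Everything in this package operates on that representation; the
measured endpoints are per-fiber cross-sectional area (CSA, μm²),
maximum Feret diameter (μm) and per-channel mean intensity.

Conventions used throughout: coordinates are 0-based, x rightward, y
downward; pixel (x, y) occupies the half-open square [x, x+1) × [y, y+1);
object identity is 4-connected (fibers separated by membrane must not
merge through a shared diagonal corner); calibration is a single
isotropic pixel size in μm/pixel (default 1.0, i.e. pixel units).

## ROI conversion

`labels_to_rois` traces the crack boundary — the polyline of pixel
*corners* separating object from non-object — rather than a contour
through pixel centers. Directed boundary edges keep the object on a fixed
side; after interior holes are filled (a fiber's CSA is defined by its
outer membrane outline; filled pixel counts are logged) every corner has
a unique continuation, so the walk is deterministic. Collinear runs are
merged, so a rectangle is 4 vertices and an L-tromino 6. Consequences
used by the tests: the polygon's shoelace area equals the pixel count
exactly (integer equality), and rasterizing the polygon back through the
half-open convention (pixel centers at half-integers are never on the
integer-coordinate boundary) reproduces the pixel set exactly for
hole-free objects.

ROIs serialize to the ImageJ binary format (big-endian, magic `Iout`,
polygon type 0, int16 bounding box and relative vertex arrays), zipped
one entry per ROI, names zero-padded to at least 4 digits so FIJI's ROI
Manager sorts them stably. Non-polygon entries (points, lines, ovals) are
skipped with a warning on read.

## Label erosion

Membrane-trained segmenters place boundaries on the bright membrane,
inflating CSA — on real Laminin-stained sections the reported effect of a
4-px erosion was a ~30 % drop in mean CSA, and our synthetic pipeline
reproduces that direction (~33 % with a 3-px absorbed membrane and 4-px
erosion). Erosion is defined per object on the raster: keep the pixels
whose exact Euclidean distance to the nearest non-object pixel strictly
exceeds the radius, with the image border treated as background (a
border-clipped fiber erodes on its cut edge too). This is equivalent to
binary erosion with a Euclidean disk structuring element, which the test
suite uses as an independent oracle. Per-object independence guarantees
objects never gain pixels and never merge; monotonicity and nesting
across radii follow from the distance-transform definition. Objects
eroded to nothing are dropped but always reported (original ID, area,
status); silent loss would bias CSA distributions. Erosion can split an
object at a thin neck — the batch pipeline runs
`split_disconnected_labels` afterwards, which keeps the original ID on
the largest component and gives fragments fresh IDs, so every measured
object is one 4-connected region and IDs stay traceable to the input.

The radius is a user parameter: the appropriate value depends on stain
and magnification and is chosen by visual inspection. The default is
4 px; no automatic selection is attempted.

## Object-matched Dice

Two label images of the same section do not share IDs, so Dice is
per matched object pair: build the ref × pred intersection-area table,
assign greedily in descending intersection order, one-to-one, ties broken
by ascending (ref_id, pred_id). Greedy rather than Hungarian: it is
deterministic, fast for thousands of objects, and exact in the
near-bijective regime that segmentation comparison lives in (the test
suite verifies equality with the exhaustive optimum on small shifted-
partition instances). Each matched pair scores 2·|A∩B|/(|A|+|B|);
unmatched reference objects score 0 and enter the mean (the mean is
reference-centric); unmatched predicted objects are counted separately
but not averaged. The reference must contain at least one object,
otherwise the mean is undefined and an error is raised.

A caution about combining erosion with Dice: eroding *both*
segmentations by one common radius cannot undo a systematic difference
in how much membrane each absorbed — the disagreement ring survives
while the objects shrink, so Dice falls. What raises agreement is
eroding each segmentation by a radius matched to its own absorption
(per-stain radii chosen by inspection), which is how the package's tests
exercise the effect (0.915 → 0.993 on the standard fixture).

## Downscale benchmark

For each scale factor s ∈ (0, 1]: downscale the intensity image with
area-weighted (anti-aliased bilinear) interpolation, run the segmenter
with diameter hint round(base_diameter · s) (floor 1; explicit per-factor
overrides are supported because published diameter choices are not always
proportional — e.g. a hand-picked 8 px where proportionality gives 6),
upscale the predicted labels to full size by nearest-neighbor (preserving
IDs), and score against the full-resolution reference. With the baseline
segmenter on the standard 150-fiber fixture the mean Dice decays
monotonically: 1.0, 0.97, 0.89, 0.69, 0.33 for 1×, 0.5×, 0.2×, 0.1×,
0.05×.

## Baseline segmenter

`threshold_watershed_segment` represents classic intensity-based
segmentation: binarize the membrane (Otsu or fixed threshold), distance-
transform the interiors, seed a watershed at regional maxima of the
distance map with minimum separation diameter/2 (suppression applied per
connected interior component, so adjacent small fibers do not silence
each other), flood to the membrane, then apply minimum-area and
border-exclusion filters. It is deterministic, scores mean Dice ≥ 0.95
(typically 1.0) on the uniform regime, and degrades monotonically with
staining heterogeneity — the mechanism that motivates shape-aware
segmenters on fixed tissue. External segmenters plug in through a shell
command template with {input}/{output}/{diameter} placeholders; no
network is bundled.

## Synthetic sections

The generator emulates what matters to this pipeline and nothing more:

- **Geometry.** Fiber areas are i.i.d. lognormal in μm² (default
  μ_log = 7.2, σ_log = 0.35: median ≈ 1340 μm², mean diameter ≈ 41 μm at
  1 μm/px — healthy adult mouse TA scale). Seeds are placed by
  radius-aware dart throwing, pixels assigned by multiplicatively
  weighted (Apollonius) Voronoi via k-nearest candidate seeds, seeds
  optionally moved to centroids (`relaxation_iters`, default 2), and
  per-cell radii rebalanced for 6 further sweeps so realized areas track
  their targets. Target cell areas are pre-inflated by the expected
  membrane loss (perimeter ≈ 3.7·√A, one membrane half-band per side) so
  the *ground-truth labels* — cells minus membrane, membrane pixels
  labeled 0 — follow the requested distribution. With the frame unset
  the generator sizes it to fit; fixing width/height rescales all areas
  to fill the frame. Measured log-areas recover μ_log and σ_log within
  a few percent at n = 150–500.
- **Staining.** "uniform" (snap-frozen-like): constant membrane
  intensity (default 200), dark interiors. "heterogeneous"
  (PFA-fixed-like): a smooth multiplicative field — white noise,
  Gaussian-filtered at `heterogeneity_scale_px` (default 80 px),
  rescaled to [1−a, 1+a] — modulates the membrane, while the interior
  carries a constant unspecific haze (default 30) *independent* of the
  field, so local membrane/interior contrast genuinely collapses where
  the field dips. Optional additive Gaussian noise on top.
- **Presets.** `control` (μ_log 7.5), `regenerating_small` (μ_log 6.2,
  wider σ), `dystrophic_mixed` (bimodal mixture) are pure-data parameter
  bundles for distribution-shift experiments.

All randomness flows through the spec's single seed; output is
bit-reproducible. What the generator does **not** model: optics (PSF,
out-of-focus light), myonuclei, adipocytes, real vessel morphology
(`random_vessel_mask` provides round blobs only, as a fixture for the
false-positive check), non-convex fiber shapes, and section-wide
illumination gradients. Passing tests on these sections therefore
demonstrate correctness of the measurement/evaluation machinery and the
direction of staining/erosion effects — not segmentation performance on
real microscopy.

## Morphometry details

CSA is exactly `area_px · pixel_size_um²`. Feret diameter is the maximum
pairwise vertex distance over the convex hull of the traced outline.
Channel means are computed over the (possibly eroded) pixel mask —
erosion precedes intensity quantification, so membrane signal does not
bleed into fiber typing. Typing: a fiber is "I" if only the type-I
channel mean exceeds its threshold, "IIa" if only the type-IIa does,
"hybrid" if both (ambiguity is preserved rather than argmax-resolved),
"unclassified" if neither; thresholds are user-supplied or derived per
channel by Otsu on the per-object mean distribution. CSA histograms use
half-open bins [0, w), [w, 2w), … with default width 500 μm² (published
bin edges are not standardized; the width is a parameter), and can be
normalized to per-image fractions for across-animal averaging; group
summaries should average per-image means (each animal one point).

## Numerical and I/O choices

Label images are written 16-bit, promoted to 32-bit when IDs exceed
65535; reads reject RGB and floating-point data rather than guess.
Batch CSVs fix floats to 6 significant digits so identical inputs give
byte-identical outputs. Degenerate inputs have defined behavior: empty
label images measure to an empty table, an empty reference makes mean
Dice an error (not NaN), zero-radius erosion is the identity, polygons
with fewer than 3 distinct vertices are rejected.

## Problem sizes in tests

The standard fixtures use 150 fibers (~494² px) for pipeline properties
and 500 fibers (~900² px) for distribution recovery; erosion-oracle and
Dice-invariance property tests run on 100 random 64×64 / 48×48 images.
These sizes give stable statistics for every asserted property while
keeping the full suite fast on one CPU.

## Known limitations

- Greedy matching is near-optimal only for near-bijective segmentations;
  heavily fragmented over-segmentation can make it miss the optimal
  assignment (the documented trade-off for determinism and speed).
- The crack-boundary tracer requires each ID to be one 4-connected
  region and raises otherwise; `relabel_connected` is the remedy.
- Anisotropic pixels are not supported; calibration is one scalar.
- The ImageJ ROI writer emits polygon-type ROIs only (no splines,
  composites or sub-pixel contours).
- The synthetic membrane has integer thickness with an effectively even
  band (odd thicknesses round down); thickness 1 is one-sided.
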