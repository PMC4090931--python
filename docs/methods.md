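# Methods

This note records the models, conventions and numerical choices behind
`bonemorph`, in the order the pipeline runs them, together with what the
synthetic phantoms do and do not establish about real sections.

## Conventions

All coordinates are 0-based, row-major, with the row index increasing
downward; points are (x, y) = (column, row) in pixels. Pixel size (µm/px)
is mandatory user input and never inferred from file metadata, because all
the method's physical constants — the 25.6 µm cell-proximity rule, the
400 µm ROI offset, the 50 µm ROI tiles, the 6 µm beads — are specified in
micrometres. Channels are one grayscale 8/16-bit file per fluorescence
role; a `ChannelStack` validates that all roles share shape and pixel size.
Ratios with a zero denominator are reported as absent (`null`), never as 0:
a section without labeled surface has no MAR, which is a different
statement from a MAR of zero, and group statistics must distinguish the
two.

## Tile assembly (k-th law nonlinear correlation)

Adjacent microscope tiles share a nominal 10–15 % overlap. For a tile pair
the method computes `ifft2(C · |C|^(k−1))` with `C = F(b)·conj(F(a))`: the
cross-power spectrum with its magnitude raised to the exponent
k ∈ [0, 1]. k = 0 is pure phase correlation, k = 1 classical
intensity-weighted correlation; the default k = 0.3 mixes the two. A
magnitude floor of 1e−12 guards empty frequency bins. The peak search is
restricted to the shift window corresponding to overlaps between half and
double the nominal one, and the peak is accepted only if its quality —
peak value relative to the all-phases-aligned spectral bound — exceeds a
floor (default 0.01); structureless strips fail this test rather than
returning a random shift. Offsets are integer pixels: the stitching error
budget (1 px) is far below any measured structure, so no sub-pixel
refinement is attempted. Global placements chain pairwise offsets down the
first column and then along rows; the redundant column chains act as loop
closures (warning above 2 px disagreement, error above 10 px). Overlap
pixels keep the first-placed tile's values; no blending or feathering is
applied. Empirically, phase-dominant exponents (k ≤ 0.3) recover every
offset of a clean 10–15 % overlap grid exactly, while k = 1 frequently
fails on thin strips — which is the reason phase information is mixed in.

## Bead registration

The TRAP/AP staining happens off the scanning stage, so those scans return
rotated, shifted and slightly rescaled (tape shrinkage). Registration is
landmark-based: 6 µm fluorescent beads spotted next to the bone appear in
both the label (reference) channels and the restained scans. Detection
thresholds the channel (Otsu), then gates connected components by
equivalent diameter within ±50 % of 6 µm and solidity ≥ 0.8; both gates act
on the half-max core of the component, because resampling blurs bead rims
and would otherwise inflate the diameter, and components touching the field
edge are dropped (their centroids are biased). Centroids are
background-subtracted intensity-weighted means. Matching aligns the two
centroid clouds coarsely (principal-axis angle candidates plus the
no-rotation candidate — the principal axis of a near-isotropic cloud is
unstable), pairs mutually nearest neighbours, and keeps the candidate whose
fitted similarity has the most pairs, a plausible scale/rotation, and the
lowest residual. The transform itself is the closed-form least-squares
similarity (rotation, isotropic scale, translation — reflections are
impossible by construction; slides are never flipped). Two beads determine
the similarity exactly, so a QC warning is logged below three. A fitted
scale outside [0.85, 1.15] or rotation beyond 32° is treated as a failed
registration rather than applied. Warping is bilinear onto the reference
grid with a validity mask for out-of-field pixels. With ≥4 beads and 0.5 px
centroid noise, recovery is within 0.2° rotation, 0.005 scale and 1 px
displacement at the bead cloud across the plausible transform range.

## Shade correction

Uneven illumination adds a slowly varying background that defeats global
thresholding. The correction is `clip(image − median(image, window), 0, ∞)`
with reflective borders. The window must exceed the largest bone feature
(default 600 µm ≈ 3× a cortical thickness) or bone is subtracted away — a
configured maximum feature size triggers a warning when violated. The
median is computed with a 16-bit rank filter (exact for integer-valued
camera counts and orders of magnitude faster than a sliding sort). The
subtraction also flattens the background to ≈0, removing minor background
noise. Under a monotone ramp, reflective padding biases the median within
half a window of the border; the interior is flat to within one intensity
unit. Shading is corrected per assembled image (not per tile); correction
is off by default and enabled per channel role in the run configuration.

## Segmentation (cascaded Otsu)

Thresholds maximize the between-class variance over a 256-bin histogram of
the observed min–max range, regardless of camera bit depth, with ties
broken toward the lower threshold; constant input is an error. The cell
channels carry three intensity populations — background outside the bone
envelope, marrow background inside it, signal — so a single global
threshold merges marrow background into the signal. The cascade re-runs
Otsu on the surviving foreground (the brighter class) only: pass one
discards the outside background, pass two separates marrow from signal.
Per-role defaults: mineral/labels/DAPI 1 step, TRAP/AP 2 steps; a step (after
the first) that would leave fewer than 16 foreground pixels is refused with
a warning and the previous mask returned. Masks are strictly nested across
steps. No morphological cleanup happens inside segmentation — that belongs
to the surface stage, keeping the thresholder testable against exhaustive
enumeration. In the pipeline, a label/cell mask covering more than 25 % of
the image is interpreted as thresholded noise of a signal-free channel and
treated as empty.

## Surface smoothing and cortex repair

For surface and ROI *geometry* (never for area measurements) the bone mask
is cleaned in two steps. Despeckling removes bone islets and fills interior
holes smaller than a 10 µm square; this carries the intent of a rank filter
run along the circumference but is exactly shape-preserving — a 2-D binary
median was rejected because it necessarily erodes right-angle corners.
Closing (dilation then erosion) with a box of side `close_um` (default
10 µm) then fills surface notches; a box rather than a digital disk because
the discrete Euclidean disk leaves unfillable one-pixel funnels at notch
mouths. Closing is idempotent and leaves smooth shapes unchanged.

Chipped or ripped cortices break the closed cortical contour and derail
ROI selection. Repair uses an elastic closed template: the convex hull
contour of the bone, resampled to 400 equal-arc-length nodes, is relaxed
iteratively — each node attracted toward its nearest bone pixel (EDT
nearest-index lookup, weight 0.4), smoothed toward its neighbours' midpoint
(weight 0.4), and re-distributed to equal arc length — until the largest
node move falls below 0.05 px (≤500 iterations; non-convergence warns and
keeps the best iterate). Runs of converged nodes farther than 1.5 px from
bone mark gaps; a gap whose template arc length is within `max_gap_um`
(default 150 µm) is bridged by a 2-px-wide polyline drawn along the
template, otherwise it is left open with a warning naming its location.
Repair only ever adds pixels.

## ROI selection

The marrow cavity is the hole of the dominant cortical component
(trabeculae inside the cavity belong to the interior — the ROI is defined
against the cortical endosteum, and the trabeculae within it are exactly
what is measured). Femur: the ROI starts 400 µm below the user-supplied
growth-plate row (no automatic growth-plate detection is attempted), stays
at least `inset_um` (default 250 µm, the midpoint of the customary
200–300 µm) from the endosteum by distance transform, and is rasterized as
50 µm × 50 µm tiles added row by row away from the growth plate until the
target area (default 2.1 mm²) is reached; shortfall beyond 15 % warns.
Vertebra: the ROI is the central region enclosed by the offset contour
770 µm inside the endosteum (the alternative peri-endosteal band reading
is selectable via `roi.vertebra_mode: band`), tiled the same way. Tile
quantization means achieved areas are approximate by construction; ±15 %
is the intended tolerance on "about 2.1 mm²".

## Projection and surface classification

The bone surface is the 8-connected boundary of the (smoothed, repaired)
mask. Normals are the negated derivative-of-Gaussian gradient (σ = 3 px) of
the mask indicator, normalized; the indicator gradient points into the bone
by construction, so its negation is marrow-ward without any orientation
fix-up. σ = 3 keeps staircase error on a 50 px-radius circle below ≈2.5°
while still resolving both faces of the thinnest phantom trabeculae.

Each connected signal component travels rigidly, one pixel per step, along
the negated normal of the surface pixel nearest its centroid. A pixel's
travel is the step at which it first overlaps bone (0 if it already does);
the surface pixel it lands on receives the hit. The component's
leading-edge distance is its minimum pixel travel; the mid-point distance
is leading edge plus half the component's extent along the travel
direction (pixels as unit cells: a 4-px band with leading edge 10 has
mid-point 12). Components whose leading edge exceeds the travel cap —
50 µm for labels, 3× the proximity rule (76.8 µm) for cell stains — are
discarded and logged, preventing marrow debris from projecting across the
cavity.

Inter-label thickness is, per double-labeled surface pixel, (first-label
distance − second-label distance) × pixel size, using leading-edge
distances by default (mid-point mode available; for equal-width bands the
two agree). Negative values (locally inverted label order) are excluded
and counted. Classification flags each surface pixel by which labels hit
it; AP/TRAP flags additionally require the originating component's
leading-edge travel to be within the proximity window (25.6 µm mouse,
67.4 µm rat). Exclusive classes (L1-only, L2-only, double, unlabeled)
partition the surface exactly; composite classes (AP∧L2 = active
osteoblast, AP without label = lining cell, TRAP without label = eroded
surface, TRAP∧L2) derive from the flags.

## Measurements and statistics

All surface ratios are class pixel counts over total surface pixels inside
the ROI. BV/TV uses the raw (unsmoothed) mask. Tb.Th is twice the mean
medial-axis distance of bone within the ROI; Tb.N and Tb.Sp follow the
parallel-plate model (they reproduce closed-form stripe phantoms:
40 µm/160 µm stripes give 20 %, 40 µm, 5 /mm, 160 µm). MS/BS uses the
convention dLS/BS + sLS/BS/2; MAR = Ir.L.Th divided by the label interval —
the default interval is 5 days (injections at day −7 and day −2), but the
published method-comparison figures divide by 7, so the interval is an
explicit configuration parameter; BFR = MAR × MS/BS in fraction form.
TRAP/TV is TRAP area inside the ROI over ROI area; TRAP_on/TRAP is the
proportion of that area within the proximity window of the surface. Group
comparison runs a two-sided paired t test per measurement with pairwise
deletion of absent values; identical groups give t = 0, p = 1, and
zero-variance nonzero differences are flagged degenerate instead of
reporting an infinite statistic.

## The phantom: what it establishes, and what it cannot

Phantom geometry is deliberately restricted to axis-aligned stripes and
circular annuli so that every ground-truth quantity is closed form —
computed from the spec's own integer pixel arithmetic (band pixel counts
over stripe perimeters), never by re-measuring the rendered raster.
Mineralization labels are bands in the marrow whose leading edge sits at a
configured travel distance from the surface, first label farther out than
the second, so the true inter-label thickness is exactly the offset
difference; label start/length fractions control the single/double/
unlabeled mix. TRAP/AP sites are disks anchored on the surface (travel
≈6 µm), on the second label, or beyond the stripe end at 40 µm (off
surface: inside the ROI but outside the proximity window). Beads render in
the label channels and reappear, transformed, in the cell channels.
Intensities use a 0–1000 working scale (background 30, marrow 110, bone
600, cells 700, labels 800, beads 1000) — the acquisition fixes exposure
manually and publishes no intensity statistics, so these are free
parameters chosen to give three well-separated populations — with additive
Gaussian noise (default sd 5) truncated at zero. A fixed seed makes
phantom output bit-identical, and the pipeline itself is deterministic, so
report JSON is reproducible byte for byte.

Default study conditions: 2 µm/px working resolution, 40 µm trabeculae,
60 µm cortices, label offsets 16/6 µm (true Ir.L.Th 10 µm → MAR 2 µm/day at
the 5-day interval), five beads in a 100 µm margin ring, four TRAP and
three AP sites. The default femur phantom is 700×700 px (1.4×1.4 mm), so
end-to-end runs use a scaled ROI target (≈0.2 mm²) with the same 50 µm
tiling and inset rules; ROI-geometry checks against the full 2.1 mm²
target use a coarser 4 µm/px, 3.2×3.2 mm phantom.

Passing on phantoms establishes the geometry and arithmetic of every
stage — thresholds equal exhaustive search, projections equal per-pixel
ray marching, fractions and rates equal closed-form truth, registration
and stitching recover known transforms — but not robustness to what the
phantom does not model: marrow autofluorescence texture, osteocyte
lacunae, partially-mineralized label lines inside the bone matrix, section
folds or tears beyond clean cortical gaps, non-rigid tape deformation
(shrinkage is isotropic scale only), or realistic bead clumping. Those
require scanned sections.

## Known limitations

* Growth-plate location is user input; the method publishes no algorithm
  for finding it.
* Rigid per-component projection (the whole component moves along one
  direction) is an interpretation; pixel-wise independent projection would
  differ on strongly curved components.
* The elastic repair bridges gaps along the outer contour; a gap repaired
  this way adds a small wedge to the interior, which downstream insets
  (≥250 µm) comfortably erode away, but a vertebral band-mode ROI close to
  the endosteum would see it.
* Tb.N/Tb.Sp inherit every assumption of the parallel-plate model.
* 2-D measurements throughout; no stereological correction to 3-D.
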