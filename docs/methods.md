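# Methods

## Pipeline model

The tool assumes brightfield immunohistochemistry in which blood-vessel
endothelium is stained brown (CD31 revealed with DAB) over a blue
hematoxylin counterstain, scanned at a known scale (μm/px). Processing
is per tile, fully deterministic, and goes segmentation → morphometry →
classification → aggregation.

**Stain separation.** Pixel intensities are converted to optical
density, OD = −log₁₀((I+1)/256) per channel, and projected onto a
three-vector basis: the hematoxylin and DAB OD unit vectors
(Ruifrok–Johnston defaults `(0.650, 0.704, 0.286)` and
`(0.269, 0.568, 0.778)`, config-replaceable) and their normalised cross
product as the residual channel. Negative DAB projections are clamped
to zero. A collinear basis is rejected as a configuration error.

**Tissue mask.** A pixel is tissue when its HSV saturation
≥ `tissue_saturation_min` (default 0.05) *or* value
≤ `tissue_value_max` (default 0.85): bare glass is bright and
unsaturated, anything counterstained fails one test. Enclosed
background holes smaller than 1000 μm² (lumina, tears) are filled;
background connected to the tile border is never treated as a hole,
so an empty tile stays empty.

**DAB threshold.** Otsu's threshold on the within-tissue DAB OD by
default, or a fixed OD (`fixed_dab_threshold`). An empty tissue mask
yields an empty stained mask with a warning, not an exception; a
constant OD field (no stain at all) likewise.

**Closing open outlines.** Endothelial rings are frequently broken by
the microtome or by discontinuous endothelium. A morphological closing
with a disk of radius `closing_radius_um` (default 2.5 μm, about half a
capillary wall) seals gaps narrower than twice the radius; the mask is
padded before closing so the raster edge behaves as an infinite
background, keeping the operation idempotent. A radius that rounds to
0 px is the identity.

**Vessel objects.** Enclosed holes of the closed mask (lumina) are
filled — a vessel is wall *plus* lumen, so "width" means the full
caliber — and 8-connected components (4-connected background) become
labelled regions. Components below `min_area_um2` (default 12 μm²,
which excludes single-pixel noise at 0.25 μm/px but keeps 5 μm
capillaries) are dropped. Regions touching the raster edge are flagged:
they count for density and stained area but are excluded from
size/shape means, since their geometry is truncated (both behaviours
config-switchable). Stained-area statistics always use the *raw*
stained mask (endothelium only), not the filled regions, reconciling
SA% with full-caliber widths.

## Descriptors

All sizes are physical: area = pixel count × mpp², lengths in μm.

- **Perimeter** is the arc length of the region boundary traced at
  iso-level 0.5 (marching squares) and smoothed with a 3-point circular
  moving average. The raw staircase contour overestimates a disk's
  circumference by ≈ 6% (roundness 1.12); after smoothing a disk of
  radius 50 px measures within ~1% (roundness 1.02) and a square's
  roundness is within 1.2% of 4/π. Larger windows flatten genuine
  corners (a square loses ~2% at window 5), so 3 is the default.
- **Length/width** are the full major/minor axes of the ellipse with
  the region's second central moments (Feret diameters are available as
  a config alternative). Degenerate single-line regions get a one-pixel
  width floor.
- **Convex references.** The convex hull is taken over the smoothed
  contour vertices (scipy ConvexHull). *Perimeter ratio* divides hull
  perimeter by contour perimeter. *Deformity* is hull shoelace area
  minus pixel-count region area: the two conventions can disagree by
  O(1 px²) on convex shapes, so tiny negative values are possible and
  treated as zero-level noise; using the rasterized convex image
  instead systematically loses sharp hull vertices (a star's tips
  rasterize ~0.8 px short, an 8% bias on its deformity).
- **Hu moments / shape factor.** The seven Hu invariants are computed
  from normalised central moments of the *filled region* (not the 1-px
  contour curve), which is numerically stable and scale-normalised;
  mᵢ = sign(hᵢ)·log₁₀|hᵢ|, with |hᵢ| < 1e−30 flagged undefined. The
  shape factor compares the region (A) against its filled convex hull
  (B): max over the index set (default all seven, configurable) of
  |mᵢᴬ − mᵢᴮ|/|mᵢᴬ|. Indices are skipped when mᵢᴬ is undefined or ~0
  (divide guard) **or** when |hᵢ| < 1e−6 on either shape: for n-fold
  symmetric regions several invariants are exactly zero in the
  continuum, and their rasterized residues are noise whose log varies
  wildly under rotation. With the guard, a 5-point star's shape factor
  is stable to < 0.5% across rotations while remaining ~10⁴ × the
  disk's.
- **Branching.** The filled region is thinned to a 1-px skeleton;
  skeleton pixels with ≥ 3 skeleton neighbours form branch pixels, and
  each maximal 8-connected cluster of them is one node. Straight or
  curved tubes and closed rings give 0; a Y- or plus-junction gives 1.
  There is no standard definition of "branching" for a 2-D vessel
  profile; this skeleton-node construction is the package's own.

## Classification and summaries

Width (equivalent-ellipse minor axis) is the classifying caliber — it
is robust to elongation. Bands are half-open with the boundary
belonging to the upper class: [3, 15) μm capillary, [15, 20)
post-capillary/metarteriole, [20, 50) sinusoid, [50, 100)
venule/arteriole, ≥ 100 vein/artery. The capillary and sinusoid
calibers are the anatomically established ones; the intermediate and
upper edges interpolate/extrapolate them consistently with vascular
physiology and are fully configurable. Vessels narrower than
`min_width` (3 μm) are excluded with a logged reason. Densities are
count / tissue-mm²; SA% per segment is the raw stained pixels inside
that segment's regions over tissue pixels; relative density/SA
normalise across segments to 100%.

## Synthetic phantoms

`render_phantom_tile` paints vessel walls at DAB OD 0.9 on a tissue
background of hematoxylin OD 0.15 (white margin optional), then adds
i.i.d. Gaussian RGB noise (default sd 4/255) — enough to exercise
thresholding without modelling scanner physics. Shape families: closed
rings, open rings (a wedge of the wall removed, emulating broken
outlines), ellipse rings, capsule tubes, Y-shaped branched tubes and
star-shaped cisterns. Every family is *calibrated* so the rasterized
filled shape's equivalent-ellipse minor axis equals the requested
caliber: rings/ellipses exactly, capsules by root-finding the drawn
width from the exact capsule second moments, branched tubes and stars
by uniform scaling against a trial rasterization (the minor axis is
exactly linear under uniform scaling). This matters because a Y of
arm length L has a minor axis governed by L, not by its local tube
width — without calibration, width-based classification of branched
vessels would be meaningless. Ground truth records the exact rasterized
area, axes, centroid, painted wall pixel count and intended class per
vessel; star cisterns carry no expected branch count (their skeletons
branch by construction).

The default 30-vessel layout (10 capillaries 8–12 μm, 5
post-capillaries 16–19 μm, 10 sinusoids 25–45 μm including branched
tubes and a star cistern, 5 venules 60–90 μm, on 0.5 × 0.5 mm at
0.5 μm/px) places vessels by seeded rejection sampling with a 10 μm
minimum gap — wider than twice the closing radius, so closing can
never merge neighbours. Open-ring gaps are sized below 5 μm so the
default closing seals them.

What the phantoms do **not** emulate: real section thickness and
out-of-focus blur, anti-aliased stain edges, stain intensity gradients,
necrosis/hemorrhage, overlapping or mosaic (partially CD31-negative)
vessels, and non-vascular DAB-positive debris. Passing phantom tests
therefore demonstrates correctness of the measurement chain under the
stated imaging model, not segmentation robustness on real slides —
threshold mode, stain vectors and closing radius are exposed precisely
because real material needs tuning.

## Problem sizes and numerical choices

Tests and the acceptance script run on 1000×1000 px tiles (0.5 × 0.5 mm
at 0.5 μm/px) and 100–200 px analytic fixtures; these sizes make the
full suite complete in well under a minute per end-to-end scenario
while keeping discretization error within the stated tolerances
(descriptor checks at 1–5%, Hu-versus-oracle at 1e−6 relative).
CSV outputs use a fixed column order and `%.6g` formatting, making
reruns bit-identical; the run manifest hashes every output file.

## Known limitations

- Vessels touching the tile border are measured on their visible part
  only; stitching across tiles is out of scope.
- Two vessels closer than twice the closing radius can merge into one
  object; the default radius keeps this below typical inter-vessel
  distances but dense hot-spots may under-count.
- Width-based classification cannot separate a 20 μm capillary-like
  tube from a small sinusoid; shape-assisted classification would be a
  natural extension.
- The Hu-based shape factor uses log-scaled invariants and is
  insensitive to which invariant dominates; it is a screening
  statistic, not a metric.
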