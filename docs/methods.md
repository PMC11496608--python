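# Methods

This note documents the models, numerical choices and limitations behind
`crownsect`. Azimuths are compass bearings throughout: 0° = geographic north
(+y), increasing clockwise, east = 90°. Coordinates are metric.

## Ingest: noise, ground, heights

**Isolated-voxel noise filter.** The cloud is binned into cubic voxels
(default edge 1 m) anchored at its minimum corner. A return is noise when
the 3 × 3 × 3 voxel block centred on its voxel holds exactly one return —
the point's own voxel counts toward the total, so a fully isolated return
(count 1) is always flagged. The filter is idempotent and invariant to
translations by whole voxels.

**Ground classification.** In place of a cloth-simulation filter, the package
uses coarse grid-minimum seeding plus TIN densification: the lowest return
per 5 m cell seeds the ground set (a coarse cell virtually always holds a
genuine terrain return even under crowns, whereas a 1 m minimum can be a
crown-base return), then a Delaunay TIN through the current ground set adopts
any return within 0.15 m of the interpolated surface. Points outside the
current hull are adopted when consistent with the nearest ground return under
a bounded terrain gradient (0.25 m/m), which lets the hull grow to the plot
edge. Three iterations suffice on the synthetic scenes. This targets stands
with minimal understory; dense shrub layers would need a proper progressive
filter. Pre-classified ground flags can be supplied instead.

**Height normalization.** Heights above ground come from linear interpolation
on the Delaunay triangulation of ground returns; outside the hull, the
nearest ground return's elevation is used. Ground returns get height 0 and
small negative heights are clamped to 0. At least three non-collinear ground
points are required.

## Crown delineation and pairing

A 2D vertical occupancy index counts occupied 0.2 m voxels per column
(returns below 1 m excluded — they are treated as understory everywhere).
The raster is lightly Gaussian-smoothed (σ = 1 cell) before the local-maximum
search; markers are maxima under a circular window (default radius 1.5 m)
with value ≥ 3. Crown extents come from a marker-controlled assignment on a
0.1 m canopy height model (per-cell maximum height, 3 × 3 median
pit-filling): each canopy cell goes to the nearest admissible marker, where
admissible means the distance does not exceed 0.6 × the marker's height.
A crown's centre is the mean (x, y) of its returns in the top 50% of its
height.

Crowns from two acquisitions are paired greedily by ascending centre
distance with a hard 2 m cut and no duplicate ids; the same scheme links pair
centres to planted-stem reference coordinates, and the mean offset vector
diagnoses systematic positioning bias.

## Stem location

Returns between 1 m and half the crown's top height are clustered with a
full-covariance Gaussian mixture on (x, y, z); the component count (k = 1..8)
minimizes BIC, with optional greedy entropy-based merging of overlapping
components (an approximation to mixture-component combination criteria;
off by default). Clusters under 5 returns are discarded. Each cluster is
scored by four metrics — distance of its centre to the crown centre, height
range, horizontal convex-hull area, and the proportion of occupied 1 m
vertical bins between 1 m and half of top height — min-max rescaled across
the clusters of that tree, with the first and third inverted, and combined as

    W = p1 + 2 p2 + p3 + 2 p4,   0 ≤ W ≤ 6.

W is invariant to affine rescaling of the raw metric units. Ties on W break
by larger cluster size, then larger vertical occupancy. When all clusters
share a raw value the rescaled value is set to 1 for everyone — constant
across clusters, so the ranking is unaffected (the divide-by-zero case of
min-max rescaling). The winning cluster's mean (x, y) is the stem; if no
cluster survives, the fall-back is the mean (x, y) of the canopy returns
above half of top height. For a paired tree the epoch whose winning cluster
holds more returns takes priority; equal counts or two fall-backs average.

The pipeline runs a **second segmentation pass** with the located stems as
markers: stems are recovered to millimetres on synthetic stands, so the
second pass puts crown boundaries between interlocking neighbours on the true
midlines, which the 0.2 m-quantized occupancy maxima cannot.

## Crown geometry

**Alphashape.** The crown surface is the boundary of the alpha complex:
Delaunay tetrahedra with circumsphere radius ≤ α (default 1 m) are kept and
the faces belonging to exactly one kept tetrahedron form a closed surface,
oriented outward via the opposite vertex of the owning tetrahedron. If the
boundary has several connected components only the largest-volume one is
kept. Volume is the signed-tetrahedron sum; surface area the triangle-area
sum. At α → ∞ this reproduces the convex hull exactly, and volume is
monotone non-decreasing in α.

**Cross-sections and azimuth distances.** Horizontal plane–mesh intersection
segments are noded (coordinates rounded to 10⁻⁶ m) and polygonized; nesting
parity resolves holes. From 1 m to the crown top every 0.5 m, the distance
from the stem to the crown edge is measured every 10° of azimuth by casting
a horizontal ray from the stem inside the stem-containing polygon. For
concave outlines the default is the **farthest** boundary crossing
(drip-line semantics); the first exit is available as an option. Heights
where no polygon contains the stem are recorded as missing and skipped in
cumulative sums.

**Wedge volumes.** A voxel grid of 0.1 × 0.1 × 0.5 m cells spans the mesh
bounding box, anchored horizontally on the stem so that the cardinal wedge
boundaries coincide with cell edges — anchoring at the bounding-box corner
lets boundary lines slice through voxel columns and biases opposite wedges
by several percent on a symmetric crown. Voxel centroids are tested against
the cross-section polygon at their mid-height (vectorized point-in-polygon),
and each inside voxel contributes its 0.005 m³ to the wedge containing its
azimuth from the stem; a centroid exactly on a wedge boundary counts half to
each neighbour. North = wedges (315–360) + (0–45); south = (135–180) +
(180–225).

**OPCR.** Faces are binned by the compass azimuth of their outward normal's
horizontal projection into 8 sectors; patches are edge-connected components
of same-bin faces with ≥ 3 faces (configurable), and the patch count is
averaged over 8 rotations of the bin boundaries 5.625° apart — the
dental-topography convention. Faces with near-vertical normals are unbinned.
The index is invariant to uniform scaling and to rotations by the bin width.

## Temporal change metrics

Per tree: largest cumulative projection azimuth per epoch (ties to the
smallest azimuth); on the vertically overlapping height classes, the azimuths
of largest growth (positive differences summed), largest loss (negative
differences summed) and largest absolute change. If all differences share a
sign, AC coincides with LG (or LL). Emulated within/between-row diameters
combine the largest individual distances, regardless of height, at
50° + 230° and 140° + 320°; whichever axis is closer to the plot's row
azimuth (mod 180°) is "within-row". Wedge change is the signed percent
change relative to epoch 1. The stem-volume model is the Tasissa
combined-variable outside-bark form, V[ft³] = 0.21949 + 0.00238 · D[in]² ·
H[ft], wrapped in metric conversions (the printed form of the metric
equation garbles the exponent placement; the implementation follows the
combined-variable D²H reading, which reproduces the printed coefficients'
roles). RMSE/NRMSE/bias/normalized-bias utilities support accuracy tables;
normalized forms divide by the observation mean.

## Circular statistics

Summaries derive from the mean resultant vector: mean direction, R̄,
variance 1 − R̄ (unitless), SD √(−2 ln R̄) in degrees. Published azimuth
tables sometimes print "variance" in degrees; this package deliberately
reports the standard unitless circular variance and degree-valued SD. An
exactly-uniform sample (R̄ ≤ 10⁻¹²) has an undefined mean, reported as
missing, never as 0°. The Rayleigh test uses Z = nR̄² with the second-order
series p-value for n ≥ 10 and a seeded Monte-Carlo null below that; its
type-I error at α = 0.05 verifies to 0.05 ± 0.01 over 10⁴ uniform
replicates of n = 100. Watson's two-sample U² uses pooled circular ranks
with midrank tie handling, the asymptotic critical-value table
(0.10/0.05/0.02/0.01 → 0.152/0.187/0.233/0.268), and an optional seeded
permutation p-value (recommended for small samples; n ≥ 8 per sample is
required).

## The synthetic stand

The generator emulates a gridded conifer plantation: stems on a rotated
grid (4.42 m within rows, 3.66 m between, row azimuth 135° or 45°,
618 stems/ha), ground returns on a sloped plane (default gradient 0.02),
and isolated noise points placed ≥ 5 m from every crown. Each crown is a
half-ellipsoid cap over a cone frustum; defaults (total height 10 m, live
crown base 4.8 m, maximum radius 1.5 m, ~5% between-tree height jitter)
describe a pre-canopy-closure stand, with the live-crown ratio (~0.5) chosen
so the below-half-height subset is dominated by stem and dead-branch
returns, as in self-pruned unthinned stands. Returns are sampled ~uniformly
in crown volume with a 35% surface-biased share, at 120 returns/m³ plus
80 returns per metre of stem — a few hundred returns/m² of crown footprint,
comparable to high-density drone scanning. Two dead-branch tufts per tree
below the live crown give the stem locator realistic competition.

Asymmetry multiplies the radius by 1 + (ratio − 1)·((1 + cos Δ)/2)^s toward
a chosen azimuth (Δ = azimuth − preferred direction). The sharpness
exponent s = 3 keeps the lobe directionally concentrated so the generating
azimuth is identifiable from sampled crowns at the 10° measurement
resolution; a flat (s = 1) lobe varies by millimetres over ±20° around its
maximum and no estimator could localize it. Ground truth (total and
per-wedge volumes, largest-radius azimuth) is computed by numerical
integration of the generating solid in polar form, which separates into a
height integral and an azimuth integral; wedge truths sum to the total
within 0.5%.

The two-epoch helper re-scans the same stems with taller (×1.15), wider
(×1.20) crowns, the crown base raised in proportion (constant live-crown
ratio under self-pruning), and a southward asymmetry of 1.3 by default —
chosen so the southern lobe fills, but does not overflow, the free southern
growing space of the default grid (the nearest due-south neighbour sits
5.74 m away versus 3.66 m across rows). Epoch-2 sampling uses independent
random substreams, so the scans are not point-matched.

**What the generator does not emulate:** occlusion and beam divergence,
intensity, multi-return structure, wind sway between strips, species
mixtures, understory, and terrain curvature. Passing tests therefore
demonstrate correctness of the algorithms under known geometry, not sensor
realism.

## Problem sizes and determinism

Default verification scales: 9 × 9 trees (81 stems, ~0.3–0.5 M returns per
epoch), 50 single trees for stem recovery, 20 crowns for directionality,
10⁴/2 × 10³ Monte-Carlo replicates for test calibration. All randomness
flows from explicit integer seeds (per-tree substreams are spawned from
(seed, tree id)), and the full two-epoch pipeline is bit-reproducible:
identical seeds produce identical output tables.

## Known limitations

- The α = 1 m alphashape bridges gaps smaller than ~1 m, so crowns that
  physically interlock are partially merged before segmentation splits them;
  drip-line distances near shared boundaries inherit that uncertainty.
- The Silva-style maximum-radius constraint uses a single height fraction
  (0.6) rather than an allometric model.
- The BIC-selected GMM is an approximation to entropy-criterion component
  selection; on well-separated synthetic clusters the two agree.
- Watson U² critical values are asymptotic; use the permutation option for
  n < 20 per sample.
- The emulated row-diameter mapping assumes the plot's rows align with one
  of the two measured axes (50°/230° or 140°/320°).
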