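# Methods

## Coordinate conventions and units

All geometry lives in plate millimetres: origin at the image top-left,
x rightward, y downward, so root depth is positive y. Pixel scales default
to 39 µm/px for root (side-view) images and 83 µm/px for shoot (top-view)
images and convert as mm = px · scale/1000. Lengths are mm, areas mm²,
diameters µm, angles degrees, growth rates % day⁻¹.

A root system is a tree of axes: exactly one order-0 primary; order-1
laterals attached to it at an arc-length position (`branch_pos_mm`);
optionally order-2 laterals on those. "Lateral" traits (length, count,
density, angle, diameter) cover order-1 axes only; *total* root length sums
all orders. A configuration switch (`include_second_order_in_lateral`)
widens the lateral-length definition if a user prefers it.

## Extraction pipeline

**Segmentation.** Roots are bright curvilinear structures on a dark,
unevenly lit background. The background is estimated by a Gaussian blur of
radius `background_flatten_radius_mm` (default 2 mm) and subtracted; the
residual is Otsu-thresholded (a fixed threshold is available for cameras
with stable exposure). Connected components below `min_component_px`
(default 20 px) are removed — condensation speckle and sensor noise.
An image with no contrast yields an empty mask plus a warning, not an
exception, so batch runs continue.

**Skeleton graph.** The mask is thinned (`skimage.morphology.skeletonize`)
and traced into an undirected multigraph: nodes are connected clusters of
skeleton pixels with ≠2 neighbours (junction clusters may span several
pixels; the node sits at their centroid), edges are the pixel corridors
between them. Edge arc length uses chain-code weights (1 per orthogonal
step, √2 per diagonal step). For downstream geometry each corridor is
smoothed by a 5-px moving average (endpoints pinned) and Douglas–Peucker
simplified at 0.5 px: the smoothing damps the ±0.5 px staircase wiggle that
survives simplification and would otherwise bias arc lengths upward by
2–3 % on curved roots; straight rods at 0°/30°/45°/60°/90° then measure
within 0.2 % of truth. Each edge also records its mean half-width from the
Euclidean distance transform of the mask.

**Gap bridging.** Droplets and scratches fragment the skeleton. Endpoint
pairs closer than `max_gap_mm` (default 1 mm) whose outward tangents both
align with the connecting segment within `max_bridge_angle_deg` (default
30°) are joined by a straight connector, greedily by increasing gap, each
endpoint used once. Perpendicular or distant fragments are never joined.

**Crossing resolution.** Two roots crossing in the 2-D projection appear as
one 4-way junction or, when they merge tangentially, as two 3-way junctions
joined by a short shared stretch (< 0.5 mm). In both cases the four outer
edges are matched into two anti-parallel pairs (opposition angle ≥ 135°)
and fused into through-going edges, so the tree extractor sees two roots
crossing, not a branch. Genuine branch points fail the anti-parallel gate
and are untouched. We deliberately do *not* break graph cycles by deleting
edges: a cycle means a root crossed another, and deleting any cycle edge
destroys one of the two — instead, the walk below consumes each edge once,
which resolves cycles into traversals.

**Tree extraction.** The primary starts at the graph node nearest the seed
point (the sowing hole, or the topmost skeleton point in the plant's lane)
with initial direction straight down, and at every junction follows the
unused edge that least changes direction. Straightest continuation — not
longest or deepest path — is the primary criterion because laterals depart
at ~50–65° while a primary bends only gradually. Edges left over at the
axis's nodes seed child axes, traced the same way, breadth-first over
branch order: every first-order lateral claims its edges before any
second-order tracing starts, so a lateral whose tip is hidden under a
crossing sibling cannot be mis-attached as a deeper child.

Terminal skeleton edges shorter than `spur_width_factor` (1.5) × the local
root diameter are discarded as thinning spurs; real laterals must also
exceed `min_lateral_mm` (0.1 mm, below the smallest lateral lengths one can
resolve at 39 µm/px but above skeletonization debris after the width-scaled
filter).

**Branch-point re-anchoring.** Skeletonization drags the junction point
along the parent and bends the lateral's first ~root-width of centreline,
which biased raw branching angles by ≈ +9°. Each lateral therefore has its
start corrected: points within max(2 × local half-width, 3 px) of the
junction are dropped, the lateral's clean initial direction is fitted over
the next 0.6 mm, and that line is intersected with the parent path to
recover the branch point. After re-anchoring the per-lateral angle bias is
≈ 2° and per-plant means are within a few degrees of truth.

**Diameters.** Mean over ~1-px-spaced samples along the axis of
(2 · EDT − 1 px) · scale, where EDT is the distance transform at the sample;
the −1 px corrects the half-pixel offset of the distance transform (a 1-px
line has EDT 1 at its centre). Samples within 2 px of any junction are
excluded because widths there measure the junction blob.

**Manual corrections.** The correction format is RSML: an RSML file whose
axes replace same-id automatic axes, add new ones, or carry a `deleted`
flag. After merging, children are re-anchored on their (possibly retraced)
parents by projection, mirroring what GUI retracing tools do. This replaces
an interactive GUI with a scriptable file contract.

## Branching angle

Defined as the angle between (a) the parent's tangent at the branch
position, pointing in the growth direction, estimated by central
differences over ±0.2 mm, and (b) the chord from the branch point to the
point 0.4 mm along the lateral (the full chord for shorter laterals).
Reported in [0°, 180°], 90° = perpendicular; mirror-symmetric systems give
identical angles. Per plant, the unweighted mean over laterals with a valid
angle is reported. Lateral diameters aggregate length-weighted instead,
because an unweighted mean over many tiny laterals would be dominated by
quantization noise.

## Depth profile, extents, ratios

The depth profile clips every segment against horizontal bin boundaries
(default 2 mm bins) measured from the root-system base — by default the
topmost root vertex (`system_top`), because plate images crop at the agar
surface; measuring from the seed point is available. Splitting is exact, so
the bins sum to total root length to 10⁻⁶ mm. Rooting depth and system
width are axis-aligned extents (not rotation-invariant, by definition);
lengths, angles and hull area are rigid-motion invariant.

The length/depth ratio divides the primary's arc length by the *primary's
own* vertical extent — not whole-system depth — so a lateral reaching
deeper than the primary cannot push the ratio below 1. Relative growth
rates use the classical logarithmic form 100 · (ln L₂ − ln L₁)/Δt days,
computed between consecutive timepoints and undefined at the first.

## Shoot traits

Rosettes are segmented by HSV windows — hue in degrees with wraparound
(a 330°–30° window includes red), saturation and value in [0, 1] — followed
by a 1-px morphological opening. Defaults (hue 60–180°, S ≥ 0.15, V ≥ 0.15)
are green-vegetation calibration values meant to be overridden per camera.
Connected components are assigned to the nearest sowing position by
centroid x-distance (hole positions are x-coordinates along the plate's top
edge); components farther than 15 mm from every position are discarded as
debris, components reaching into a neighbour's half-lane raise an overlap
flag, and rosettes wider than 24 mm raise an oversize flag (plants are only
tracked below that diameter). Projected leaf area is the pixel count times
the squared pixel scale.

## Synthetic generator

The generator is the package's study system: it produces the *conditions*
the pipeline is validated under, with full ground truth.

* **Primary**: starts at the sowing hole heading straight down, elongates at
  `primary_rate_mm_per_day` (default 3 mm/day — a typical seedling over
  three weeks), in 0.5 mm steps whose heading receives Gaussian noise of sd
  `curvature_sd_deg_per_mm` · √step (default 5°/√mm; diffusive scaling, so
  the stated sd is per mm of growth) plus a weak pull toward vertical
  (gravitropism, 0.05 per step). Growth stops at the plate walls
  (120 × 120 mm default).
* **Laterals**: initiated as a Poisson process along the primary (default
  0.4 mm⁻¹), each appearing when the primary tip passes its position,
  departing at a signed angle ~ N(53°, 8°) from the local parent tangent
  and elongating straight at 1 mm/day. Optional second-order laterals use
  the same machinery. Two presets ship the documented phenomenology of
  shoots grown inside vs outside the sealed plate (slower primary, ~1.8×
  lateral density, 63° vs 53° angles, second-order laterals present inside).
* **Nesting**: a whole-experiment growth plan is drawn once per plant and
  materialized by truncation at any age, so time series are geometrically
  nested and monotone by construction.
* **Rendering**: axes become anti-aliased strokes (primary 4 px, laterals
  2.5 px wide, intensity 200 on background 20) with Gaussian pixel noise;
  droplets are bright rings, scratches thin faint lines; the paired ground
  truth mask is the stroke support (coverage ≥ 0.5). Calibration-rod images
  (straight rods of known length at random orientation) mirror the
  reference-object accuracy check used for plate phenotyping software.
  Rosettes render as lobed disks ρ(θ) = r₀(1 + a·cos kθ) whose exact area
  π r₀²(1 + a²/2) is the truth.
* **Determinism**: one explicitly passed `numpy.random.Generator` feeds all
  sampling and rendering; identical seed + parameters give bit-identical
  systems and images. Extraction itself contains no randomness.

What the generator does *not* emulate: root hairs, intensity variation
along an axis, agar refraction, out-of-focus blur, curved laterals and
gravitropic lateral bending, overlap of roots with the hypocotyl, or plants
touching across lanes. Passing recovery tests on these images therefore
demonstrates the geometry/topology machinery, not robustness to every
optical artifact of real plates.

## Validation studies and their problem sizes

`validation.rod_length_accuracy` renders rods of 10–100 mm and regresses
measured on true length (measured R² ≈ 0.999992). `validation.recovery_study`
renders whole plants one per plate and compares extracted to true traits.
The count-exactness study runs in the *well-separated regime* — every
lateral ≥ 1 mm and branch points ≥ 1 mm apart — constructed by pruning
immature (< 1 mm) laterals from the ground truth before rendering and
rejecting plants with closer spacing. The shipped study uses 20 plants,
14-day-old systems at 0.12 laterals/mm on an 80 mm rendered plate region;
under those conditions primary length is recovered within 0.3 %, lateral
counts exactly, and the mean branching angle within ~1°. At dense mature
defaults (21 days, 0.4 mm⁻¹) laterals overlap and merge in the 2-D
projection, counts drop below truth, and — as in real practice — manual
retracing (the RSML correction path) is the remedy; this is a documented
limitation, not a target of the automatic extractor.

## Genotype analysis

CV = 100 · sd/mean with the n−1 denominator; undefined (NaN + warning) for
zero mean. Column z-scores drop constant or <2-observation columns with a
warning; missing cells stay missing. Row distances are Euclidean over
mutually observed columns rescaled by √(p/p_shared) (complete-case deletion
is a switch); a pair sharing no column is an error naming the pair.
Complete linkage is implemented directly (O(n³), trivial at tens-to-hundreds
of genotypes) so the merge contract is explicit: merge height = maximum
inter-cluster pairwise distance, ties broken by the lexicographically
smallest cluster-id pair — bit-stable across platforms; scipy's
implementation serves as an independent cross-check in the tests. Cutting
the first n−k merges yields k clusters labelled in order of first
appearance. Trait correlations are pairwise-complete Pearson with a
minimum of 3 paired observations. Whether to cluster genotype means or
per-plant values is the caller's choice; the CLI clusters genotype means,
the convention for accession panels. The heatmap (red–yellow, white =
missing, dendrogram-ordered) is presentation only.

## Numerical choices and degenerate inputs

* Polylines need ≥2 distinct vertices; consecutive duplicates are dropped.
* `point_at_arclength` tolerates 10⁻⁹ mm slack at the ends; out-of-range is
  an error.
* Ratio and density fields are `None` (CSV: empty) when their denominator
  is zero — never encoded as 0.
* An image lane with no skeleton yields an *empty* root system flag rather
  than an error; traits on it are zero lengths.
* Convex hull of <3 non-collinear points has zero area.
* 16-bit images are rescaled to 8 bits by the dtype range (÷65535), keeping
  intensities comparable across frames of a series.
* Depth-profile bin count uses a 10⁻⁹ guard so an extent that is an exact
  multiple of the bin width does not create an empty trailing bin.

## Known limitations

* 2-D projection only: roots overlapping along the optical axis merge;
  dense mature systems undercount laterals (see above).
* Primary identification assumes the primary is the straightest
  continuation from the seed; a primary kinked more sharply than a
  lateral's departure angle would be mis-split.
* The hypocotyl/seed region is not modelled; the seed point must be near
  the top of the root system.
* Shoot segmentation is threshold-based; anthocyanin-red rosettes need a
  wraparound hue window supplied by the user.
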