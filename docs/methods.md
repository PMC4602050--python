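# Methods

## Interval coding

A binary region of a 2D/3D grid is stored per occupied row as an ordered
list of maximal half-open column intervals `[start, end)`, grouped into
sparsely stored planes (an absent plane or row is empty). Coordinates are
0-based; grid shapes and dense masks follow numpy axis order, `(ny, nx)`
and `(nz, ny, nx)`. Canonical form — sorted intervals separated by strict
gaps, no empty rows or planes, adjacency merged at construction — makes
equality a structural comparison: two domains with the same voxel set
serialize identically.

The representational argument is that a typical anatomical or expression
region has boundary complexity one dimension below its bulk: a filled
disc of radius r holds ~πr² pixels but only ~2r intervals. Set operations
(union, intersection, difference) are two-pointer merges per shared row,
so their cost follows interval count, not area. The Jaccard numerator is
computed by a dedicated intersection-size kernel that walks only rows the
two operands share; the denominator uses |A| + |B| − |A∩B|. The test
suite pins every operation to a dense boolean-array oracle and asserts
the scaling claim directly (interval count of a disc grows < 6× while
area grows > 12× as the radius quadruples).

Domains optionally carry a *frame* (reference-model id plus grid shape).
Mixing frames in any binary operation is an error, never a silent
resample: comparing patterns is only meaningful inside one model's
coordinate space.

## Morphology

Dilation and erosion iterate the unit structuring element `radius` times:
a diamond (octahedron) for 4/6-connectivity, a square (cube) for 8/26.
One dilation step is the union of the domain's translates over the
element's offsets; one erosion step is the intersection of translates
over the negated offsets. Both are exact flat morphology on the infinite
grid; when the domain has a frame, dilation is clipped to the frame at
each step so behaviour at the model boundary matches a dense
implementation on a frame-shaped array. Distance transforms (integer
city-block or chessboard path counts) and connected-component labelling
are standard grid algorithms and are delegated to `scipy.ndimage` through
a dense round-trip; components are ordered by size descending with a
bounding-box tiebreak so labelling is deterministic.

## Similarity scores

* **Jaccard**: J(A,B) = |A∩B| / |A∪B| ∈ [0,1]. Undefined (an error) when
  both operands are empty. 1 − J is a metric; the suite spot-checks the
  triangle inequality on random triples.
* **LOSSST** (local spatial similarity): for a nonempty painted query q
  and an expression domain e,

      L(q, e; r) = |q ∩ e| / |q ∪ (e ∩ δ_r(q))|

  where δ_r is dilation by radius r (default 2; connectivity defaults to
  8 in 2D, 26 in 3D, exposed as a parameter). Expression further than r
  from the query neither helps nor hurts the score, so a small painted
  region scores highly against any pattern that covers it locally,
  regardless of how far the pattern extends elsewhere; L ≥ J always.
  The published description of this score names its primitives
  (intersect, union, dilation, difference) but not the formula; the form
  above is this package's declared stand-in, built from exactly those
  primitives and pinned against a dense-mask evaluation in the tests.
  Whether the original weights near-miss expression positively rather
  than only ignoring distant expression is unknown here.

Ranked queries sort by score descending with entry-id tiebreaks and
suppress zero scores. The query level defaults to the "detected"
annotation (the superset of all strength levels).

## Syn-expression clustering and occupancy

Every pattern is compared with every other pairwise, giving a symmetric
unit-diagonal Jaccard matrix; row i is pattern i's *signature*.
Agglomerative clustering runs on signature rows — by default UPGMA
(average linkage) on Euclidean distances, both configurable, with a
direct 1−J distance mode for comparison. Clustering signatures rather
than raw overlaps groups patterns with similar overlap *profiles*, which
tolerates patterns that are similar without sharing identical voxels.
Cutting the tree at k removes the k−1 highest merges. Identical
signatures merge at height 0; for tie-free inputs the partition at any k
is invariant to input order (asserted by permutation tests).

A node heatmap is the occupancy map of the node's members: per-voxel
counts of containing domains. Occupancy display classes are count 0, 1,
2 and ≥3, rendered blue, green, yellow and red respectively; analysis
outputs carry raw counts and the colour mapping lives only in the
renderer. Per-voxel lookup returns the sorted gene list of patterns
containing the voxel plus the anatomy layers covering it.

No default cluster count is asserted as correct; k is the caller's
choice.

## Expression mapping

The warp model is a Delaunay triangulation of the source landmarks with
one affine map per triangle (estimated exactly from the three vertex
pairs), continuous across shared edges and interpolating every landmark
pair to numerical precision. The inverse direction triangulates the
target points. Points outside the respective convex hull have no image
(NaN). This piecewise-affine model deliberately stands in for the
production constrained-distance-transform warp used by curated atlases;
the `WarpMesh` interface isolates it so another registration model can
be slotted in.

Warped domains are rasterised by *inverse mapping*: each target pixel
centre is pulled back to source coordinates, rounded, and tested for
membership — this cannot produce holes. Source pixels outside the mesh
hull are dropped with a logged warning; a nonempty in-hull domain that
rasterises to nothing is an error. Because all levels share the same
pull-back, level nesting survives mapping exactly.

Signal extraction thresholds in HSV space (the usual choice for
purple/blue ISH chromogens): each strength level is a hue arc (wrapping
allowed), a minimum saturation and a value range. Nesting — the strong
band inside moderate inside weak inside detected — is validated at
configuration load, which makes the subset chain of extracted domains a
structural guarantee rather than a post-processing step. Thresholds are
always supplied as data (JSON), never hard-coded. Trapping artefacts
(stain pooled in cavities) are handled as a manual exclusion domain
subtracted from every level; no automatic detection is attempted.
Discrete strength levels do not capture continuous expression gradients.

## Virtual sectioning

A section is parameterised by a fixed point (voxel coordinates), yaw
about the volume z axis, then pitch about the rotated x axis, then roll
about the resulting view normal (intrinsic rotations; composed matrix
`Rz(yaw)·Rx(pitch)·Rz(roll)`), a signed distance along the normal, a
zoom (section pixels per physical unit) and a viewport with an in-plane
origin offset. The angle order is a convention choice — covered by a
rotation-matrix oracle test so any future change is caught. The
coordinate system is right-handed with x = column, y = row, z = plane;
the section v axis points down to match image display. Anisotropic voxel
spacing is applied before rotation, so oblique sampling happens in
physical space.

Grey sections sample with nearest or trilinear interpolation
(out-of-volume pixels take a configurable background, default 0);
zero-angle sections with integer distance reproduce stored slices
exactly. Domain sections use nearest-voxel membership so they remain
binary and interval-codable, and match a dense mask cut with the same
transform voxel-for-voxel.

Compound objects are ordered lists of named, *freely overlapping* layers
with per-layer colour, alpha and visibility; compositing is back-to-front
source-over blending. The one-label-per-voxel restriction applies only
to index-image export, where overlap is a policy decision: `error`
(default) aborts at the first shared voxel with its coordinate,
`priority` lets the last layer win and reports the overridden count.
Tiles (default 256 px) are crops of the full composited section, edge
tiles padded with background, and mosaic back to the full image exactly.

## Synthetic fixtures

The generators are pure functions of their seed and define the
conditions all tests run under.

* **Phantom volumes**: a smooth ellipsoidal grey body (light smoothed
  noise added) with three nested anatomy layers; the spherical variant's
  intensity depends only on radius, making section statistics
  rotation-invariant — the oracle for oblique sampling.
* **Expression sets**: groups of patterns derive from disjoint ellipsoid
  templates laid out along the y axis with half-axes scaled to the
  inter-group spacing (members of different groups can never touch, so
  between-group Jaccard is exactly 0). Members toggle a `jitter`
  fraction of template voxels, restricted to the one-voxel boundary band
  (morphological noise, the way biological boundaries vary), keeping
  within-group Jaccard near (1−2j)/(1+2j) ≈ 0.67 at j = 0.1 — far above
  the between-group score, so planted-partition recovery is provable
  empirically across seeds. Defaults: 3 groups × 5 patterns, jitter 0.1,
  frame 100×120×80 voxels (big enough to exercise interval compression,
  small enough for seconds-scale tests). Members of one group share the
  same "strong" core (the once-eroded template), a simplification of
  real level annotation.
* **Assay cases**: an analytic ellipse (half-axes ~38–44 × 30–36 px on a
  160×160 model frame) defines ground truth; a seeded affine map
  (rotation ±15°, scale 0.92–1.08, translation ±6 px about the centre)
  defines the true data→model deformation. The data image colours
  in-region pixels with a purple chromogen tone (±8 intensity noise,
  kept inside the "strong" HSV band) on a pale background that no band
  matches; ≥8 landmarks sit on a grid sampled from the true affine.
  End-to-end recovery is limited only by boundary rasterisation
  (roughly half a pixel over a ~230 px perimeter against a ~4,000 px
  area), so mapped-versus-truth Jaccard stays above 0.95.

What the fixtures do *not* emulate: real embryo morphology, staining
chemistry, imaging physics, non-affine tissue distortion, annotator
variability. Passing tests demonstrate algorithmic correctness on
controlled geometry, not curation accuracy on real assays.

## Numerical and design choices

* Half-open 0-based intervals (stated in the serialization) rather than
  the inclusive 1-offset convention of older systems: fewer off-by-one
  hazards, and Python/numpy-native slicing.
* `.ivd` files are JSON for inspectability (gzip-wrapped `.ivdz` for
  bulk), written byte-stably (sorted keys, fixed separators); readers
  reject non-canonical interval lists instead of repairing them. No
  claim of compatibility with any binary atlas format.
* NIfTI is the only dense 3D exchange format (x fastest on disk; arrays
  transposed to `[z, y, x]` in memory); spacing round-trips through the
  header zooms.
* Euclidean distance transforms are omitted: no operation here needs
  them.
* Tolerances: warp landmark interpolation is exact to 1e-9; the affine
  warp-versus-dense-resample oracle allows 1% pixel disagreement (edge
  rasterisation); spherical-section mean intensity is rotation-invariant
  to 1%.
* Problem sizes in the default test run are chosen for seconds-scale
  feedback: oracle sweeps use ~10×12 and ~5×7×9 grids (200 instances per
  operation class), planted-group recovery uses a 24×48×32 frame over 20
  seeds, and the throughput check ranks 1,000 patterns on the full
  100×120×80 frame.

## Known limitations

* 2D-to-2D mapping only; volumetric (3D) registration of optical
  projection tomography data is out of scope.
* The LOSSST form is a documented stand-in (see above).
* Colour thresholding assumes a chromogen that separates from background
  in HSV; counterstained or brightfield-noisy images may need
  per-dataset threshold configs.
* Interval set algebra is pure-Python per row; it comfortably handles
  thousands of patterns per query but is not tuned for full-resolution
  (micron-scale) volumes.
* No HTTP tile serving, caching or multi-resolution pyramids; tiling is
  single-scale.
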