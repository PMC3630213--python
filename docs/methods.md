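# Methods

This note documents the models, numerical choices and limitations behind
`leafsurf`. It states no empirical result that the test suite does not
itself compute.

## Shape from focus

**Model.** A surface point is in focus in the slice whose focal plane
matches its height, and in-focus texture has the strongest local edges.
Sharpness is the magnitude of the standard 3×3 Sobel pair,
√(Gx² + Gy²), computed per slice with edge-replicated borders (zero
padding would create spurious frame maxima). A pixel's aggregate
sharpness in slice k is the maximum Sobel magnitude over a w×w window
(default w = 5) centered on it; the height estimate is the argmax over
slices.

**Choices.**
- Ties in the argmax go to the lowest slice index: deterministic and
  stable under reordering (the permutation-covariance property is
  tested).
- Pixels whose aggregate sharpness stays below ε = 10⁻⁶ (on [0, 1]
  normalized stacks) in every slice carry no height information; they
  inherit the height of their nearest textured pixel (Euclidean distance
  transform). The elastic map later smooths any residual error. Note that
  a perfectly uniform background next to a textured leaf is *not* fully
  textureless: defocused texture leaks a weak gradient across the
  boundary, so the fill path only triggers on genuinely flat regions.
- Intensities are min-max normalized per stack: sharpness comparisons are
  within-stack only, so absolute intensity scale carries no information.

**Calibration.** Lateral scale (µm/px) is a user-supplied configuration
value. Axial scale comes from a reference object of known thickness
imaged beside the specimen: µm/slice = thickness / |idx_top − idx_bottom|,
symmetric in the two indices.

## Elastic-map surface model

**Energies.** With S the in-mask height-map points (µm), node grid Y,
grid edges E and ribs R (triples of consecutive nodes along rows and
columns):

- U_Y = (1/|S|) Σ_j Σ_{s∈K_j} w_s ‖s − y_j‖², K_j the points hosted by
  (nearest to) node j — an *average* weighted square, so λ and µ do not
  need rescaling with point count;
- U_E = λ Σ ‖y_i − y_j‖² (stretching, zero rest length);
- U_R = µ Σ ‖y_i − 2y_j + y_k‖² (bending, discrete second difference).

Fitting alternates the assignment (E) step with an exact minimization (M)
of the total quadratic in Y — one sparse Cholesky-type solve per
coordinate. Both steps are non-increasing in the total energy, which is
asserted on every fixture.

**Coordinate normalization.** The cloud is internally rescaled so its
bounding-box diagonal has unit length. λ and µ therefore act on
dimensionless coordinates and one default works across magnifications
and leaf sizes.

**Boundary anchoring (default).** Zero-rest-length stretching springs
contract the free grid roughly 10% inside the data bounding box, which
drops edge trichomes off the fitted surface. By default the boundary
ring's (x, y) coordinates are therefore pinned to the data bounding box
(Dirichlet rows in the x and y solves; z is always free). The
unconstrained fit remains available (`anchor_boundary=False`) and is the
variant that matches the textbook small-penalty limits (per-host
centroids, exact plane interpolation).

**Defaults.** Grid 30×30, λ = 0.001, µ = 0.01, tol = 10⁻⁵ relative
energy change, max 100 iterations. The stiffness defaults were chosen on
the surface-recovery property the tests enforce: on a leaf-scale Gaussian
dome (30 µm relief, 60 µm width, 300 µm domain) with 2 µm height noise, a
30×30 fit must track the dome to an RMS below the noise. A 10× stiffer
setting (λ = 0.01, µ = 0.1) flattens that dome by ~9 µm and fails the
property; the adopted values give RMS ≈ 0.7 µm while still suppressing
the noise (tested in `test_acceptance.py`).

**Degeneracies.** With λ = µ = 0 an empty host node makes the system
singular; the fit aborts naming the empty nodes. Queries up to 2% of the
domain extent outside the fitted (x, y) domain are clamped to the domain
edge (annotations are marked on the full image while the surface covers
the segmented leaf, so edge trichomes may sit a pixel or two outside);
queries farther out raise a domain error.

**Evaluation and meshing.** The surface is bilinear in each grid cell
(cells located by inverse-bilinear Newton iteration, so mild grid warp is
handled exactly). Triangulation splits every quad along the same
lower-left→upper-right diagonal — deterministic, with the diagonal choice
a second-order artifact. For statistics the mesh is restricted to
triangles whose centroid lies inside the leaf outline, so areas, Voronoi
cells and geodesics live on the leaf proper rather than its bounding box.

## Geodesics

First-order fast marching on the triangle mesh: the Kimmel–Sethian
planar-front update inside each triangle, with the edge (Dijkstra) update
as fallback when the causality condition fails (obtuse configurations).
Two accuracy refinements:

- **Exact seeding.** Vertices within min(12 mean edge lengths, 5% of the
  mesh extent) of the source are seeded with their exact straight-line
  distance, removing the dominant point-source discretization error. The
  cap keeps chord seeds from shortcutting bends on coarse meshes; on a
  surface with bend radius ρ the seeding error is ≈ s³/(24ρ²) for seed
  radius s — negligible at the scales used here. Targets inside the
  seeded zone return the chord directly.
- **Relaxation sweeps.** After the marching pass, Gauss–Seidel sweeps of
  the same local solver run to a fixed point (≤ 10 passes, tolerance
  10⁻⁹ × field scale), erasing ordering errors where a vertex was
  accepted off a fallback value.

Measured accuracy (asserted in the acceptance tests): ≤ 0.5% against
planar Euclidean on a flat 200×200 crosshatch mesh, ≤ 2% against the
great-circle arc on a radius-100 µm spherical cap at the same resolution.
Relative accuracy claims apply to separations well above the mesh edge
length; at separations of a few edges the answer is resolution-limited
(the unit tests sample accordingly). Grid meshes intended for geodesic
benchmarks should use the crosshatch (4-triangles-per-cell) split, whose
richer stencil directions roughly halve the direction-dependent error of
the single-diagonal split.

## Voronoi tessellations

- **2D:** scipy's planar Voronoi; cells of convex-hull generators are
  unbounded, flagged non-finite and excluded from statistics; finite
  cells are clipped to the leaf polygon (shapely intersection).
- **3D-Euclidean:** every mesh triangle is assigned via its centroid to
  the nearest generator in 3D; the cell area is the summed 3D triangle
  area. Cells touching the mesh boundary are the on-surface analogue of
  unbounded cells and are likewise excluded. The centroid-assignment
  granularity error shrinks with mesh resolution (the flat-mesh
  tessellation agrees with the clipped planar one within 2% at 120×120).
  Geodesic-metric Voronoi is out of scope.

## Leaf frame, meta leaf and statistics

The frame is two user-supplied points: the origin (middle of the petiole
at the lamina base) and the longitudinal-axis tip. origin→tip defines
the +y direction *and* the unit of both axes, so the tip maps to (0, 1);
the x-axis is the perpendicular with the same scale. All meta-leaf
statistics are invariant (to 10⁻¹⁰) under rigid rotation + translation +
uniform scaling of a leaf together with its frame. An optional
centroid-based axis suggestion is provided for when the axis is not
marked manually. Base distances are emitted both normalized and in µm.

Only leaves with one to six mature (class 4) trichomes are analyzed;
leaves failing the rule are listed with reasons, never silently dropped.
Densities (count / 3D leaf area) and morphometrics are per-leaf samples;
Voronoi areas and geodesic nearest-neighbor distances are pooled per
trichome within a genotype.

**Wilcoxon rank-sum.** Two-sided; exact null distribution when
n_a + n_b ≤ 20 and the pooled sample has no ties (verified against full
enumeration for all n_a, n_b ≤ 6), otherwise the normal approximation
with tie correction and continuity correction
(z = max(0, |U − µ_U| − ½)/σ_tie). Identical samples give p = 1 under
this convention. p-values are reported raw; a Benjamini–Hochberg column
is included for reference but does not drive the significance flags.
Class-4 tests are suppressed with an explanatory note, because selecting
leaves by mature-trichome count makes that comparison meaningless.

## Synthetic scenes

A scene is a named surface family (plane, tilted plane, Gaussian bump,
cylinder section, hemisphere cap) with band-limited uniform-noise texture
(default contrast 0.5, darker than the constant 0.9 background as in
bright field), imaged under an idealized defocus model: slice i blurs
each pixel with a Gaussian of σ = σ₀ + k·|i − h(x, y)| (defaults σ₀ = 0.5
px, k = 0.3 px/slice) — the simplest monotone model under which
argmax-of-sharpness recovers h. Blur is evaluated by linear interpolation
in a precomputed bank of uniformly blurred textures (σ step 0.5 px). The
default scene is a 200×200 px, 60-slice gently domed leaf (40-slice
relief), matching a 10× objective's field at ~1 µm/px.

Trichome patterns are hard-core (minimum-distance) processes inside the
mask, classes assigned by longitudinal zones — class 4 nearest the tip,
class 1 nearest the base, each zone widened by an overlap parameter
(default 0.25; 0 gives fully separated zones).

**What a green test does not establish.** The generator has no optical
PSF, no trichome pixels (annotations are coordinates), no z-positioning
jitter beyond the blur model, no specular highlights, and elliptical
leaves only; segmentation and focus performance on real micrographs is
not certified by these fixtures. Reported discriminations between
synthetic "genotypes" exercise the machinery, not biology.

## Known limitations

- The elastic map is a height field over (x, y): strongly folded leaves
  (multivalued z) are out of scope.
- First-order geodesics: errors grow on meshes with many obtuse
  triangles; use crosshatch or finer grids for metrology.
- 3D Voronoi areas inherit triangle-centroid granularity.
- The boundary-anchored fit slightly biases boundary z when the data are
  steep at the leaf edge (interior accuracy is unaffected).
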