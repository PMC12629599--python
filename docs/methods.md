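# Methods

## Shape representation

A cell is an ordered, implicitly closed polyline (`Contour`) in physical
units (pixels for image-traced contours unless a pixel size is supplied).
Orientation is normalized to counterclockwise on construction so outward
normals are well defined; consecutive vertices closer than 1e-12 of the
bounding-box diagonal are treated as duplicates and dropped (the relative
tolerance keeps validity checks scale invariant).  Two kinds are
distinguished: `polygon` (the vertex list is meaningful — corners) and
`sampled` (a dense sampling of a smooth curve).  The distinction matters
only for descriptors that read the vertex list itself (γ_p); all
Minkowski quantities treat both identically.

## Minkowski functionals and tensors

The scalar functionals are area W₀ (shoelace), boundary length W₁, and the
integrated contour curvature W₂.  For polylines the curvature is
concentrated at vertices, so W₂ is the sum of signed exterior angles —
exactly 2π for every simple CCW contour; no spline fitting is attempted
because nothing downstream needs pointwise curvature.

Tensor-valued extensions **W**_j^{a,b} integrate symmetrized products
r^⊙a ⊙ n^⊙b with r measured from the area centroid (translation-covariant
variants are out of scope).  Per-edge integration is exact: n is constant
and r linear on each edge, so Gauss–Legendre of the appropriate order
integrates the polynomial integrand without error; the interior (j = 0)
integral uses Green's theorem the same way.  For j = 2 the vertex
contribution integrates n(θ) over the fan of normal directions swept
between adjacent edges (the rounded-corner limit), with r frozen at the
vertex — the natural polygonal limit of the smooth definition.  Rank is
capped at a + b ≤ 8, which covers every p ≤ 8 analysis.

## p-atic order parameters

ψ_p is computed by the per-edge closed form (1/2π) Σ L_e e^{ipθ_e}; edges
of sampled contours are treated the same way, converging with vertex
density.  q_p = |ψ_p|/ψ₀ and ϑ_p = atan2(Im ψ_p, Re ψ_p)/p + π/p.  Two
conventions are fixed for reproducibility:

* ϑ_p is reduced to the canonical interval [0, 2π/p), and the +π/p shift
  is always applied (it makes the p = 2 director coincide with the
  negative-eigenvalue eigenvector of the traceless normal tensor, i.e. the
  structure-tensor elongation axis — `director_from_tensor` checks this
  identity to 1e-8).
* when q_p < 1e-12 the director is meaningless (atan2 of numerical noise)
  and is reported as NaN; such angles are excluded from director
  statistics.

Note an algebraic subtlety: because of the +π/p shift,
q_p e^{ipϑ_p} = −ψ_p/ψ₀ identically.  The coarse-graining below uses
q_p e^{ipϑ_p} literally; the global sign cancels in every magnitude
reported.

## Alternative descriptors

γ_p weights vertex directions by |r_i|^p about the vertex-mean centroid
(the convention of the tracking tools it originates from; the
area-centroid variant is available behind a flag for sensitivity checks).
Its orientation uses the two-argument arctangent even though the classic
definition prints a single-argument arctan — the quadrant-correct form
changes no magnitude, which is all the comparisons use.  γ_p is refused
for `sampled` contours: a dense sampling has no distinguished vertices.

Bond order Ψ_p^bond averages e^{ipθ_b} over bonds to neighboring cells'
area centroids.  Two adjacency definitions are provided and must be named
in any report, since they generally differ: `shared_interface` (two labels
adjacent iff they share ≥ `min_interface_px` 4-connected boundary pixel
pairs, default 2, suppressing single-corner contacts) and `delaunay`
(triangulation of centroids, 3×3 ghost tiling with deduplication for
periodic boxes).

## Coarse-graining

Q_p(x) averages q_p e^{ipϑ_p} over cells whose area centroid lies
*strictly* inside the circle of radius R around grid point x (Θ(0) = 0);
Γ_p(x) averages γ_p with vertex-mean centroids.  The square grid starts at
the domain's lower-left corner with spacing = mean R_cell rounded to 3
significant digits (a documented choice where "close to the mean cell
radius" leaves slack); periodic domains use minimum-image distances and a
grid covering [0, w) so no point is duplicated.  Empty circles carry NaN
and are excluded from means.  Cells flagged as boundary-touching are
excluded by default because their contours are truncated by the field of
view.  Grid points are sampled on the full rectangle whether or not cells
cover them; for non-periodic domains points within R of the border simply
see fewer cells.

The radius scan reduces each (frame, R) field to a scalar before taking
time statistics (mean, population std, s.e.m. = std/√n_frames over
frames).  The default reduction is the **spatial mean of |Q_p(x)|**: in
the one-cell-per-circle limit it equals the mean q_p of the sampled cells,
and for disordered tissues it decays with R as opposing directors cancel
within each circle — the quantity whose p = 2 and p = 6 curves are
compared in crossover analyses.  The alternative reduction |spatial mean|
(modulus of the complex average, `summary="abs_mean"`) additionally
cancels across grid points and measures *global* alignment; for a
disordered tissue it is near zero at every R.  The two answer different
questions and the choice visibly changes the curves, hence both are
exposed and the default documented here.  Crossovers are located by linear
interpolation of sign changes of the difference of the two curves;
coincident curves return a sentinel.

## Independence statistics

The sample distance correlation uses the classical biased V-statistic:
double-centered pairwise-distance matrices A, B; dCov² = mean(A∘B);
dCor = dCov/√(dVar_x dVar_y) ∈ [0, 1].  Constant samples are degenerate
and report 0 with a flag.  The permutation test shuffles y with a seeded
generator and uses the add-one p-value (1 + #{≥ observed})/(1 + n_perm),
so p ∈ (0, 1]; the default is 999 permutations and the seed is recorded in
every report.  Summary statistics use the population (divide-by-n)
standard deviation — the records are a census of the analyzed cells, not
a sample.  Kernel density estimates use a Gaussian kernel with Scott's
bandwidth (exposed as a parameter).

## Synthetic data

The generators supply every input the analyses need:

* regular and corner-rounded regular polygons (tangent circular arcs;
  corner radius up to the inradius, which yields a circle) and ellipses —
  calibration shapes with known spectra;
* the collapse family: quadrilateral A=(0,0), B=(1,0), C=(0.5,√3/2),
  D = C + s(A−C) + bulge·n̂.  With bulge = 0 the traced contour is the
  triangle for *every* s, isolating pure vertex-list sensitivity; with
  bulge > 0 the shape genuinely deforms and converges as bulge → 0;
* star-convex random blobs (seeded Fourier radius perturbations) for
  invariance suites;
* Voronoi tissues: seeded uniform points, tessellated periodically via
  3×3 ghost tiling or bounded via mirror-image seeds (which clips cells
  exactly to the box), with optional Lloyd relaxation (seeds moved to area
  centroids) driving the packing toward hexagonal order.  Determinism
  under (seed, parameters) is asserted in tests.
* `rasterize` labels each pixel by the cell containing its center
  (minimum-image resolution of seam pixels in periodic boxes), producing
  the label images the IO path consumes.

What the generator does *not* emulate: active cell motility, neighbor
exchanges, cell division, segmentation noise beyond pixelation, and
intensity-based imaging artifacts.  Passing tests therefore demonstrate
correctness of the measures and their documented contrasts on
polygonal/rounded cells of tunable regularity, not biological realism of
any particular monolayer.

## Label-image pipeline

Contours are traced along the pixel cracks (half-open pixel convention),
so the traced polygon's area equals the label's pixel count exactly;
coordinates are converted from image space (row 0 on top) to y-upward
mathematical coordinates on load.  The staircase of a traced disk carries
spurious 4-atic order (q₄ > 0.2 for a 50 px disk); a circular moving
average over the crack vertices (odd window, default off, window 7 in the
examples) restores isotropy to q_p < 0.02.  Checkerboard corner contacts
are resolved by the left-turn rule, keeping each 4-connected component's
boundary separate.  Labels with several 4-connected components trigger a
warning and keep their largest component.

`polygonalize` places polygon vertices at lattice corners where ≥ 3
regions meet (image exterior counts as background) — a junction-based
polygonal approximation of the kind used by vertex-tracking tools.  Cells
with fewer than three junctions fall back to their traced contour with a
warning.  Polygonalized cells systematically score higher q₆ than smoothed
contours of the same cells, a descriptor artifact the comparison command
quantifies.

## Problem sizes and numerical choices

Default analyses in the examples and tests use 120–200-cell tissues,
rasterized at 12–25 px per unit length, with 2–5 frames and radius ladders
R/R_cell ∈ {1, 2, 4, 8} — sizes chosen so every statistical contrast
(decay of coarse-grained magnitudes, Lloyd ordering, polygon-vs-smooth
bias, independence tests) is resolved well beyond its frame-to-frame
scatter while each script completes in seconds.  Permutation tests default
to 999 permutations (199 in the quick tests).  All randomness flows
through `numpy.random.default_rng` seeds recorded in outputs.

## Known limitations

* Non-convex pathologies: continuity guarantees for Minkowski tensors are
  proven for convex bodies; no special handling is attempted for extreme
  non-convex contours beyond the invariance tests.
* W₂-based tensors on polylines depend on the vertex-fan convention above;
  they are provided for completeness and unused by the order parameters.
* `shared_interface` adjacency needs a label image; polygon-only frames
  must use `delaunay`, and the two can disagree near fourfold vertices.
* The crossover radius is descriptor- and convention-dependent (see the
  radius-scan reduction discussion); it should be read as a property of
  the chosen pipeline, not of the tissue alone.
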