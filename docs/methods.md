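# Methods

## Scope and model

`lvmorph` converts a time-series of segmented left-ventricular endocardial
surfaces (triangle meshes or star-shaped point clouds) into a sequence of
structured quadrilateral surface meshes that share one connectivity array
(1-to-1 vertex correspondence), plus temporal densification and
quality/accuracy/physiology reporting. The output is a moving-boundary
description for CFD; the package does not segment images and does not run
flow simulations.

Time is the nondimensional cycle coordinate `T ∈ [0, 1)`, `T = 0` at
end-diastole. Lengths are millimetres, volumes mm³.

## Isoparametric mapping

Each patch is mapped by three tensor-product second-order Lagrangian
polynomials in the canonical coordinates `(x, y) ∈ [-1,1]²` (nine monomial
terms per output coordinate). The coefficients solve three shared-matrix
linear systems enforcing exact interpolation of the control-point (CP)
correspondences; quad-4 uses the bilinear subset, quad-8 the serendipity
basis. Numerics: LU with partial pivoting, a condition-number guard at
1e12 (beyond it the CPs are reported degenerate). Because the basis
restricted to a patch edge depends only on that edge's three CPs, two
patches sharing an edge produce identical subdivided edge nodes — this is
what makes the welded multi-patch meshes conforming, and it holds for any
subdivision count.

Quadratic edges leave a tangent discontinuity where patches meet; the
package's remedy is patch density (a cubic-edge variant is not
implemented). A regression test verifies the worst inter-patch dihedral
jump shrinks when the patch count quadruples on a smooth target.

## Sac template and morphing

The generic shape is a truncated pyramid, open at the top: an `m×m`-patch
cap at the apex and four `m×n`-patch lateral faces, welded. Patch count is
`4mn + m²`; welded CP count is `2E + 1` (disk topology), reproducing
41/153/593/1705 CPs for the four published layouts. The layout itself is
not published; this family was adopted because it reproduces all four
(patch, CP) pairs exactly. The cap square defaults to half the top width
(`cap_fraction = 0.5`).

Scale fitting is automated (the original procedure is manual): bisection
on a ray-crossing parity containment predicate finds the largest
scale-down with all CPs inside every frame and the smallest scale-up with
all CPs outside, each padded by a 5 % margin. Open targets are closed by
centroid fans over their border loops for the parity test only.

Each CP is projected along its inner→outer segment; the intersection
nearest the inner point is taken (the inner point is inside by
construction, so the first crossing is the endocardium). Misses fall back
to the nearest surface point with a warning; more than 10 % of fallbacks
is treated as a mis-pose and raised as an error.

Two geometric choices matter in practice and are package decisions:

* **Template width.** A centroid ray through a template-rim CP crosses the
  endocardial wall (instead of escaping through the open base) only if the
  template rim lies laterally outside the widest target rim.
  `suggest_base_width` therefore proposes 1.2× the largest lateral
  diameter of the frames about the long axis; the CLI uses it when no
  width is configured.
* **Rim snapping.** A rim CP's trajectory crosses the wall slightly below
  the open border, at a frame-dependent height, which biases volumes and
  hence the EF. After projection the rim CP row is re-projected onto the
  border loop of the (clipped) target nearest the template's top plane.
  Disable with `snap_rim=False`.

Frames are clipped for sac morphing at `sac_fraction` of the apex→base
axis with a plane perpendicular to the axis (whether the original work
clips by plane or geodesic height is unstated). The default fraction is
0.8; the published values are 0.5 (US) and 0.55 (MRI), none for CT.
Mesh connectivity is computed once from the template geometry (welding the
subdivided patch lattices) and re-evaluated per frame, so element arrays
are byte-identical across frames by construction.

## Y-junction

The construction is described over figures in the source work; this
implementation fixes the under-determined steps as follows. The ridge is
the intersection of the surface with the plane spanned by the
saddle-to-saddle direction and the vertical, trimmed to the shorter arc
between the saddles. Per conduit, the bifurcation ring is the ridge plus a
horizontal semicircle radially projected onto the wall (the second conduit
traverses the ridge reversed, which keeps the welded orientation
consistent). Ring ladders interpolate linearly between the ring scaled
down by 0.5 about its centroid and an ε-circle (ε = 0.1 mm) at the valve
centroid, phased by the angular positions of the ring points about the
conduit axis to avoid twist. Conduit length defaults to the
bifurcation-to-centroid distance.

Enlarged rings are built by expanding every small ring concentrically to a
common absolute radius (a multiplier of the bifurcation-ring radius,
geometrically doubled from 1.2 until all points clear the surface, capped
at 10×). A common *factor* instead of a common radius would never clear
the wall at the ε-ring row. Projection is again first-crossing with
nearest-point fallback; row 0 is pinned to the exact on-surface
bifurcation ring so the shared-wall CPs of the two conduits weld
bitwise-exactly.

Grids must have an odd row count (`N` odd) and an even circumferential
count `K = k_ridge + k_semi − 2`. Landmarks after frame 0 are tracked
automatically: saddles by nearest point; valve centroids (interior points)
by the displacement of their nearest wall point when the current frame is
available — pure nearest-point mapping would glue an orifice center to the
wall.

## Connector and assembly

Border renumbering minimizes the summed pairwise distance over all cyclic
rotations and both directions (exhaustively — counts are small — with a
deterministic tie-break at the node nearest the other border's start). The
band is one ring of quad-9 patches through the two borders and the
surface-projected midpoint polyline; its subdivision must be even (default
2) so the band's border nodes coincide exactly with the input border
nodes, which the 1e-6 mm assembly weld relies on. After welding, element
orientations are harmonized by breadth-first propagation, and the assembly
must leave exactly two border loops (the valve openings).

## Temporal interpolation

Per-node, per-coordinate cubic splines over `T`: `natural` is a scipy
cubic spline (natural end conditions, or the periodic spline when the
cycle wraps); `bezier` is interpreted as a C¹ cubic Hermite interpolant
with Catmull–Rom finite-difference tangents, since keyframes must be
reproduced, not approximated. Keyframes are emitted bit-exactly;
intermediate frames are equally spaced per interval; connectivity is
copied unchanged.

## Metrics

Equiangle skewness uses the four corner angles of the linear element (the
quadratic in-element curvature is ignored, matching what a CFD solver sees
in the exported mesh); a zero-length edge flags the element at 1. The gate
is max ≤ 0.9 and mean ≤ 0.25 per frame. The automated repair relaxes the
nodes of offending elements toward their neighbour centroid, re-projects
them to the target surface, and iterates (≤ 100 passes); non-convergence
is reported, not raised.

Distances are exact point-to-triangle minima, computed brute force in
chunks (bit-identical to the naive double loop; no spatial index, so the
oracle equivalence is trivial). The six classification intervals default
to interior edges 0.001 / 0.01 / 0.1 / 0.35 / 1.0 mm — only the lowest
edge is published; 0.35 mm is a typical CT pixel, 1 mm the coarse
threshold.

Volumes integrate signed tetrahedra against the origin and report the
absolute value (segmentation tools disagree on orientation); open borders
are closed by centroid fans — the closure rule for the open sac is a
package choice, as the original volume algorithm is unstated. EF uses
max/min frame volumes rather than fixed frame indices, since frame 0 is
end-diastolic in the published data but not guaranteed in general input.

## Synthetic data

`make_breathing_sac` generates a truncated half-ellipsoid (default
semi-axes 25/22/45 mm — a normal adult LV scale), open at the base plane,
uniformly scaled per frame along a cosine volume curve renormalized over
the sampled grid so the extreme frames realize the target EF (default
0.58, near the published segmented value) exactly; 15 frames matches the
published CT temporal resolution, and 0.2 mm Gaussian surface-normal noise
emulates segmentation roughness at sub-pixel scale. What it does not
emulate: trabeculae and papillary muscles, torsion (nodes are not material
points), non-uniform regional wall motion, or valve-plane tilt. A green
end-to-end test therefore establishes correct geometry processing and
volumetry on a smooth, star-shaped chamber — not anatomical fidelity.

`make_bifurcation_target` is a marching-cubes extraction of the implicit
union of a 20 mm dome and two vertical 6 mm tubes, with analytic saddle
points, valve centroids and tube axes as landmark ground truth.
`make_pointcloud` reconstructs star-shaped surfaces via the convex hull of
unit directions about the centroid (a spherical Delaunay), emulating
manually segmented ultrasound point clouds. All generators are pure
functions of their arguments including the seed.

## Known limitations

* Star-shaped chambers are assumed by the projection constructions and the
  point-cloud reconstruction; strongly concave targets will trip the
  fallback-quality errors rather than produce bad meshes silently.
* The 41-CP sac template is too coarse for volumetry: its EF estimate on
  the breathing-sac fixture is biased by ≈ +0.012 (the working resolutions
  153/593 CPs recover EF within 0.01).
* Landmark tracking is nearest-point based; large inter-frame motion
  (> 10 mm) raises a tracking-lost error instead of guessing.
* Exported linear quads discard the quadratic in-element geometry.
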