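# Methods

This note documents the models, numerical choices and limitations behind
`neurotess`. Units are micrometres throughout; meshes are right-handed with
outward-oriented faces.

## Input model

A morphological tracing is a rooted tree of points (position **t**, radius
*r* > 0, SWC type). Two soma dialects are normalised on read: a single
type-1 point maps directly to (centre, mean radius); a k-point type-1
ring/contour maps to (centroid, mean distance from centroid), with the raw
contour preserved for round-trips. Neurite roots are the non-soma points
whose parent is a soma point. Zero-length segments (a child coincident with
its parent) are collapsed at read time with a warning, because downstream
orientation vectors require nonzero direction vectors. Coordinates are
taken as-is (no unit rescaling).

## Soma: volumetric icosphere + static linear FEM

The FEM domain is a subdivided icosahedron. At subdivision level L the
surface has 20·4^L triangles; the interior is filled with L concentric
copies of the surface triangulation (radii k/(L+1)·R) plus the centre
vertex. Shell pairs are connected by triangular prisms, each split into
three tetrahedra with the index-based diagonal rule (each quad side face is
cut through its globally smallest vertex index), which makes adjacent
prisms agree on shared faces and yields a conforming, positively oriented
tetrahedral mesh; the innermost shell is coned to the centre. Level 0 is
the icosahedron coned to its centre (13 vertices, 20 tets). The default
soma level is 2 (162 surface vertices, 320 surface triangles), a surface
density comparable to typical low-poly soma spheres.

Surface triangles are paired into quads by a maximum-weight perfect
matching on the triangle dual graph, weighted by coplanarity of the merged
pair, with a tiny index-based tie-break for determinism; for ≤ 24
triangles an exhaustive search is used. The matching depends only on the
subdivision level and is cached per level. Quad cycles start on the shared
diagonal, so fan-splitting a quad at its first vertex reproduces exactly
its two source triangles (areas and volumes are conserved by
construction).

Each neurite anchor (insertion point = first tracing point of the neurite,
start radius) is assigned a surface quad by a globally optimal assignment
(Hungarian) on the angular distance between quad-centroid direction and
insertion direction. Because all four vertices of an anchor quad receive
Dirichlet constraints, assigned quads must be vertex-disjoint, not merely
distinct: if an optimal assignment contains two quads sharing a corner,
the costlier of the two is forbidden and the assignment re-solved.

The anchor quad's vertices are prescribed onto a planar square centred at
the insertion point, normal to the (soma centre → insertion point)
direction, with half-diagonal equal to the start radius so the refined tube
radius is continuous at the junction. The square's in-plane rotation keeps
the original corner order and winding sense (minimal twist), and corners
are built as exact antipodal pairs so the square's centroid is the
insertion point bit-exactly.

All other vertices solve static equilibrium of linear isotropic elasticity
on linear (constant-strain) tetrahedra, assembled sparsely and solved with
a direct sparse factorisation after row/column elimination of the
constrained DOFs. There are no body forces; the pull is realised purely as
displacement boundary conditions, because the target quad geometry is
prescribed exactly by the neurite diameter. Consequences used by the test
suite: the solution is independent of Young's modulus (default 1.0,
nominal); linear tets reproduce affine fields exactly (patch test);
mirroring the domain and constraints mirrors the solution. Poisson's ratio
(default 0.3, admissible (−1, 0.5)) controls swelling: ascending ν sweeps
produce non-increasing soma volumes for a fixed anchor set. Strong pulls
at coarse levels can invert a few interior tetrahedra; this is reported as
a warning (the surface mesh remains closed and 2-manifold, which is what
the pipeline guarantees; the volumetric mesh is discarded after
deformation).

## Coarse neurites

Orientation vectors: standard point o = normalize(d₀ + d₁) (parent and
child directions), fork o = normalize(d₁ + d₂) (two child directions,
parent-independent), ending o = d₀. Hairpins (sums below 1e−12) fall back
to a deterministic orthogonal (cross with the smallest-component axis).

Section-quads are centred at the tracing point, normal to o, with
corner-to-centre distance r (the quad is inscribed in the cross-section
circle, which makes the refinement's radial displacement exactly
consistent with the corner attributes at y ∈ {0, 1}). In-plane rotation is
fixed by parallel transport of the previous frame (project both axes onto
the new section plane and re-orthonormalise, preserving handedness),
seeded from the deformed anchor quad — a rotation-minimizing frame that
prevents tube twist. Corners are generated as antipodal pairs, so the
corner centroid reproduces the tracing position bit-exactly.

At a fork, an extra vertex v′ = t + r·o is inserted and the fork
section-quad is split along one diagonal into two stitching quads
([v0,v1,v2,v′] / [v0,v′,v2,v3] or [v0,v1,v′,v3] / [v′,v1,v2,v3]). The
separating plane contains the fork point and both children; the chosen
diagonal is the one whose endpoints lie *farther* from that plane. The
plane holds the branch bisector and the direction in which the children
part, so the distant diagonal is the crotch shared by both child tubes
while each near corner faces one child (when the children are symmetric
about a diagonal plane, that diagonal is selected). Each stitching quad is
assigned to the nearer child and becomes that child's starting ring; the
stitching quads are scaffolding, not faces — the child tubes' lateral
quads close the surface (verified by edge census). Points with three or
more children (legal SWC, not produced by the generator) are handled by
recursive binary splitting in child-id order, with a log notice.

Consecutive rings are joined by 4 lateral quads; endings are closed by one
cap quad. Every vertex carries its tracing point's attributes (id, centre,
radius, orientation, radial normal); every lateral quad's four vertices
map to exactly two tracing points, cycle-ordered so the first two belong
to the segment's first point. Assembly makes windings globally consistent
(BFS over shared edges, global flip to positive volume). For a tree
morphology the result is a closed 2-manifold with χ = 2.

## Refinement

The three tessellation substages are emulated on the CPU:

1. **Levels.** Importance (≥ 1) lives on tracing points; a vertex inherits
   its point's importance. Outer level of an edge =
   round_half_up(w·I(a) + (1−w)·I(b)) clamped to [1, max_level], with the
   weight attached to the lower vertex id so both incident patches compute
   the identical value; w defaults to 0.5 and the inner level uses uniform
   quarter weights over the four corners (both exposed in `RefineConfig`;
   default max_level 64). Because the rule is a pure function of the
   edge's two vertices, shared edges — including soma-hole rings and cap
   rims, whose vertices carry the adjacent neurite point — agree on both
   sides without any special neighbour-adoption rule.
2. **Subdivision.** Each patch is subdivided in the unit square: per-edge
   boundary points at the outer levels plus a regular interior grid
   ((inner−1)² points), triangulated by a parameter-space Delaunay
   triangulation; connectivity is cached per level tuple. The
   triangulation covers the square with total parametric area 1 and no
   duplicate coordinates; with uniform levels k it is exactly the
   (k+1)×(k+1) grid (8 triangles at k = 2), and level 1 returns the
   original quad, making uniform importance 1 an identity refinement.
3. **Evaluation.** Lateral-patch vertices: v = r·n + c with the cubic
   Hermite centerline c(y) (tangents õᵢ = s·|t₁−t₀|·oᵢ, s = 1 by default),
   linear radius interpolation, and n the normalised bilinear corner
   normal (slerp along the two x-edges as fallback when the bilinear sum
   degenerates below 1e−9). Soma quads and caps have no two-point segment
   and pass through bilinearly. Shared-edge points are computed once per
   undirected edge with canonical weights ((o−i)/o, i/o) measured from the
   lower vertex id, by a canonical owner (the lowest-index lateral patch if
   any); corners reuse the coarse vertices. This welding makes shared-edge
   vertex sequences bit-identical by construction — `audit_crack_freeness`
   verifies it by re-evaluating every dual-evaluable edge from both sides
   and returning the maximum discrepancy (0.0 in all tests).

Length-scaled tangents suppress the loop/stall artifacts of fixed-magnitude
tangents: the regression test shows zero stalls over thousands of
randomised orientation pairs for the adaptive rule, versus frequent stalls
when the tangent magnitude ignores segment length.

## Metrology

Topology reports use a directed-edge census (closed: every undirected edge
in exactly two faces; manifold and consistently oriented: no directed edge
repeated), Euler characteristic V − E + F, and union-find components.
Volumes use the divergence theorem over fan-triangulated faces. The
Hausdorff summary samples each surface (face-referenced vertices plus
area-weighted uniform samples, seeded) against an exact point-triangle
distance in both directions; `maximum` estimates the Hausdorff distance,
`mean` the average symmetric surface distance. Distances below 1e−12 of
the bounding-box diagonal are clamped to zero. Mesh I/O keeps quads as
quads (OBJ/OFF/PLY, ASCII and binary little-endian PLY); per-vertex
tracing attributes travel in a CSV sidecar with hex-float fields for
bit-exact round-trips.

## Synthetic morphologies

The generator emulates the gross statistics of laboratory tracings: a
spherical soma (default radius 8 μm), 0–n first-order neurites leaving
along a golden-section spiral of directions (indexed by neurite number
only), tortuous paths (default perturbation 0.25 per step), segment lengths
~8 μm, initial radius 1.2 μm tapering by 0.92 per point, and binary
branching with configurable probability and depth; at least one fork is
guaranteed (deterministically forced on the first neurite) whenever
branching is enabled. Each neurite draws from its own counter-based RNG
stream, so adding a neurite does not perturb existing ones. What it does
*not* emulate: soma contours, varicosities, spines, non-binary forks,
unit noise or registration artifacts of real reconstructions — so passing
tests demonstrate the pipeline's geometric and topological guarantees, not
biological realism of any particular cell type.

## Problem sizes and defaults

Library defaults: soma level 2, ν = 0.3, refinement max_level 64, uniform
weights, tangent scale 1. The test and acceptance runs use soma level 1–2,
neurons of 2–6 neurites (~20–60 tracing points) and refinement levels
1–10; the topology census covers 100 seeded morphologies in the tests and
30 in the acceptance script, the crack audit 1000 and 200 random
importance fields respectively, and Hermite endpoint exactness 10⁵ random
segments — sizes at which every property is exercised end-to-end while the
suites stay quick on a single CPU.

## Known limitations

- The anchor-square in-plane rotation and the parallel-transport seed are
  one conforming choice; tube twist is minimised but not canonical.
- Tubes of adjacent neurites or sharp hairpins can interpenetrate (the
  mesh stays watertight but not embedding-free), as with any sweep method
  that does not perform global collision resolution.
- The Hermite centerline can overshoot the coarse tube near sharp traced
  turns (that is the smoothing working as designed); tangent_scale < 1
  tames it at the cost of straighter paths.
- Soma quads and caps refine bilinearly (no curvature added); soma detail
  is set by the icosphere level, not by importance.
- FEM element inversion is possible under extreme pulls at coarse levels;
  it is warned about and does not affect the surface guarantees.
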