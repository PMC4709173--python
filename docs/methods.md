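# Methods

## Model

A *plane widget* α is a bounded planar quad with center **c** and oriented
unit normal **n**; it contributes the linear implicit function

    F(p) = n · (p − c)

whose sign splits space into inside (F < 0, the side the normal points away
from), the plane itself (F = 0), and outside (F > 0).  A *clipping path* is
an ordered chain α₁…α_N of widgets in which consecutive planes meet in a
hinge line — the polygonal cutting surface a surgeon drags along an
osteotomy or tumor boundary.  Boolean union of implicit functions is the
pointwise minimum, intersection the pointwise maximum; both are again
implicit functions, so a binary tree over plane leaves encodes one scalar
field.  Clipping a triangle surface by that field separates the model into
the part to remove and the remainder.

## Reduction to 2D and the combination algorithm

The chain is transected by an auxiliary plane β perpendicular to α₁ and α₂
(normal = normalized cross product of their normals).  Every widget plane
traces a line on β and every hinge traces a point, so the path collapses to
a polyline P₁…P_{N+1}; the free endpoints P₁ and P_{N+1} are placed on the
side of the end hinges where the end widgets' own quads extend (only the
direction matters — both end pieces act through their infinite extension
rays P′).  Each widget's inside region projects to a consistent side of the
polyline; the orientation step flips individual normals so all inside
witnesses (segment midpoints nudged along the projected −normal) lie on the
majority side.  The witness side is the *local* side of the traversal
direction, which coincides with the global two-sides partition of the
extended polyline whenever that partition exists, and remains well defined
on worst-case paths whose end-segment extensions legitimately cross the
core.  Hinge-to-hinge self-intersections are rejected.

The combined function is built recursively on index ranges (i, j):

* i = j — the single widget's function;
* j − i = 1 — the pair combines with ∩ if P_{j+1} is inside α_i, else ∪;
* otherwise a split index k is found by walking k from j downward while the
  split at k is *inadmissible*, then the two halves (i, k−1) and (k, j)
  combine with ∩ if P_{k+1} is inside α_{k−1}, else ∪.

A split at k is admissible when the two subchains' extended boundaries meet
only at the shared hinge P_k.  Concretely two ray/polyline incidence tests
are probed, and the loop steps down while either hits:

1. the ray from P_{k+1} through P_k (the head extension the right subchain
   would gain) against the left chain P′_i P_i … P_{k−1}, for i+2 ≤ k ≤ j;
2. the ray from P_{k−1} through P_k (the left subchain's tail extension)
   against the right chain P_{k+1} … P_{j+1} P′_{j+1}, for i+2 ≤ k ≤ j−1.
   (At k = j the tested chain is a single ray whose supporting line passes
   through P_j, so the test is vacuous there.)

Inside tests are strict sign tests on the 3D plane functions of points
lifted from β; values within tolerance of zero count as inside, so ties
break toward intersection.  All 2D predicates use an absolute tolerance of
1e-9 × the polyline bounding-box diagonal; collinear overlap of positive
length counts as a hit, intersections within tolerance of a vertex shared
between the tested entity and the chain are excluded, and an intersection
parameter landing exactly on a range boundary emits a warning and counts as
a hit (deterministic tie-break).

The admissibility form of the loop conditions is this package's design
choice, validated in two ways: the produced sign field agrees with an
independent 2D side oracle (crossing parity of a finite connecting path to
an inside witness — exact for any simple curve, including unbounded ones,
where even–odd ray casting is not well defined) at 100% of ~1e5 sampled
points over 100 random chains; and the documented cost laws below hold
exactly on the closed-form fixture families.  One consequence is accepted
deliberately: on a 4-widget chain of the first worked-example type the
recursion produces ((a1 ∪ a2) ∪ (a3 ∩ a4)) — the associativity-rebracketed
form of the right-deep tree that a broader line test would produce.  The
two trees evaluate identically at every point (min is associative); the
broader test that yields the right-deep form can also walk past the only
valid split on meandering chains and corrupt the sign field, which a
clipping tool cannot afford.  A decision trace (which test fired at which
k, and every split and operation) is recorded on the cost counter for
inspection.

## Cost model

Every base-case call (one or two widgets) costs 1; a composite call costs 1
plus one unit per loop iteration plus its children.  On convex fans the
loop never fires and the cost is exactly 2N − 3 (verified for N = 3…30).
The worst case — every composite call walking k all the way down — costs
(N+3)(N−2)/2 + 1; it is realized by the look-back fan fixture, in which
every edge from the third on points directly away from the midpoint of the
segment two places back, so each edge's backward extension crosses a piece
present in every probed head chain (verified exactly for N = 4…22; beyond
N ≈ 23 the fan converges toward self-similarity and consecutive widgets
become near-parallel, which the path validator rejects).

The average-case simulator draws a uniform split position I ∈ {1,…,N−1} and
charges a problem of size N ≥ 2 the full sub-chain scan N plus the two
subproblems, with T(1) = 1.  Its expectation is exactly N(2H_N − 1), i.e.
mean cost per widget 2H_N − 1 ≈ 1 + 2(ln N + 0.577 − 1).  This follows the
recurrence the average-case analysis solves; the instrumented counter of
the real algorithm charges only realized loop iterations (and T(2) = 1), so
the simulator is the model of the *analysis*, not a second measurement of
the implementation — the measured laws above are.

## Mesh clipping

The clip is a scalar-field split (marching-triangles style): per-vertex
values of the combined expression; triangles entirely on one side pass
through; mixed triangles are cut on their sign-crossing edges at
t = s_a/(s_a − s_b), producing a triangle and a quad, the quad triangulated
by its shorter diagonal.  Cut vertices are cached per edge so the two
halves share identical coordinates and total surface area is conserved to
float round-off.  Vertices within eps of the zero set (default 1e-9 × the
mesh bounding-box diagonal) are ON and duplicated into both halves; a
triangle with all vertices ON goes to the inside half only.  Cut faces are
left open — no capping — matching how clipped surgical models are rendered.
Thickness limiting is one more Boolean intersection with the (optionally
reversed) thickness plane widget, which bounds the removed slab so the
model is not cut through; sequential clipping feeds each stage's remainder
to the next and returns all removed parts plus the final remainder.
Connected components are computed on the vertex-adjacency graph.

## Synthetic data

No deposited data exists for this problem; every mesh and path is
generated.  Meshes are icospheres and radially displaced icospheres
(ellipsoid; ellipsoid with a Gaussian bump along +z as the tumor stand-in;
two disjoint lobes for component tests) — watertight, deterministic, with
subdivision controlling triangle count (subdivision 4 ≈ 5 000 faces is used
for the clipping checks; the method is linear in faces, and nothing in the
verified properties depends on density).  Paths are authored as 2D
polylines and lifted to 3D widget chains by extrusion plus a rigid
transform: a circular-arc fan (convex best case), the look-back fan (worst
case), the three worked 4-widget figures, a closed 29-widget regular
enclosure around the bump (clipped as an open chain whose first and last
polyline points coincide on the closing hinge; validated against a
point-in-polygon oracle), three stacked shallow 3-widget stages that cut a
sphere into four parts, and random chains (turn angles rejection-sampled in
±(10°, 150°), segment lengths 0.5–2, rejected unless the polyline including
its extension rays is simple so the side oracle is well defined).

What the fixtures do not emulate: anatomical geometry (no CT reconstruction,
no mesh defects, no million-triangle models), widget quads with interactively
dragged corners, and paths whose consecutive planes are near-parallel or
mutually perpendicular in the degenerate sense the method itself excludes.
Passing tests therefore demonstrate the correctness of the combination
algebra, its cost behaviour, and the clipping machinery — not robustness to
malformed clinical meshes.

## Known limitations

* Only plane leaves; no general implicit surfaces.
* One thickness plane; complex far-side tumor surfaces can leave residue.
* Moebius-like paths and three mutually perpendicular adjacent widgets are
  rejected, not solved.
* The worst-case fixture family is exact only to N ≈ 22 (see above).
* Closed enclosures reuse the open-chain recursion; their correctness is
  guarded empirically by the polygon oracle, not by construction.
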