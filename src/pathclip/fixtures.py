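"""Synthetic meshes and clipping-path configurations for tests and demos.

Everything is generated procedurally and is bit-reproducible from
(kind, params, seed).  Clipping paths are authored as 2D polylines (the
transection-plane view, which is what fixes the Boolean-combination
topology) and lifted to 3D widget chains by extrusion perpendicular to the
authoring plane, followed by a rigid transform so the paths are genuinely
three-dimensional.  The worked-example, convex-fan and staircase fixtures pin down *which*
loop conditions fire, not any particular coordinates.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .errors import GenerationError, InvalidInputError
from .implicit import ImplicitExpr, Leaf, Node, Op, PlaneWidget
from .clip import TriangleMesh
from .path import Chain2D, ClippingPath, EntityKind, line_hits_polyline

__all__ = [
    "gen_mesh",
    "gen_path",
    "gen_random_chain",
    "gen_random_expr",
    "lift_chain",
    "MESH_KINDS",
    "PATH_KINDS",
]

MESH_KINDS = ("SPHERE", "ELLIPSOID", "BLOB_BUMP", "TWO_LOBES")
PATH_KINDS = (
    "CONVEX",
    "STAIRCASE_WORST",
    "EXAMPLE1",
    "EXAMPLE2",
    "EXAMPLE3",
    "ENCLOSURE",
    "COMPLEX4",
)

# fixed rigid transform used to lift the deterministic fixtures off the axis
# planes (any proper rotation works; the combination topology is intrinsic)
_CANON_ROT = trimesh.transformations.euler_matrix(0.31, 0.22, 0.13)[:3, :3]
_CANON_SHIFT = np.array([3.0, -2.0, 5.0])


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def gen_mesh(kind: str, params: dict | None = None, seed: int = 0) -> TriangleMesh:
    """Watertight stand-ins for CT-reconstructed anatomy.

    kinds: SPHERE (radius, subdivisions), ELLIPSOID (radii, subdivisions),
    BLOB_BUMP (ellipsoid body with a protruding bump along +z — the tumor
    stand-in; radii, bump_height, bump_width, subdivisions), TWO_LOBES (two
    disjoint spheres in one vertex list; radius, separation, subdivisions).
    """
    params = dict(params or {})
    subdiv = int(params.get("subdivisions", 3))
    if not (0 <= subdiv <= 6):
        raise InvalidInputError("subdivisions must be in 0..6")

    if kind == "SPHERE":
        radius = float(params.get("radius", 1.0))
        if radius <= 0:
            raise InvalidInputError("radius must be positive")
        m = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
        return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))

    if kind == "ELLIPSOID":
        radii = np.asarray(params.get("radii", (2.0, 1.5, 1.0)), dtype=float)
        if (radii <= 0).any():
            raise InvalidInputError("radii must be positive")
        m = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
        v = np.asarray(m.vertices) * radii
        return TriangleMesh(v, np.asarray(m.faces))

    if kind == "BLOB_BUMP":
        radii = np.asarray(params.get("radii", (2.0, 1.5, 1.0)), dtype=float)
        height = float(params.get("bump_height", 0.6))
        width = float(params.get("bump_width", 0.35))
        if (radii <= 0).any() or height <= 0 or width <= 0:
            raise InvalidInputError("invalid blob parameters")
        m = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
        d = np.asarray(m.vertices)  # unit directions
        # radial ellipsoid distance plus a Gaussian bump around +z
        r_ell = 1.0 / np.sqrt(((d / radii) ** 2).sum(1))
        ang = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
        r = r_ell * (1.0 + height * np.exp(-((ang / width) ** 2)))
        return TriangleMesh(d * r[:, None], np.asarray(m.faces))

    if kind == "TWO_LOBES":
        radius = float(params.get("radius", 1.0))
        sep = float(params.get("separation", 3.0))
        if radius <= 0 or sep <= 2 * radius:
            raise InvalidInputError("lobes must be disjoint: separation > 2*radius")
        m = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
        v = np.asarray(m.vertices)
        f = np.asarray(m.faces)
        va = v + np.array([-sep / 2, 0, 0])
        vb = v + np.array([sep / 2, 0, 0])
        return TriangleMesh(np.vstack([va, vb]), np.vstack([f, f + len(v)]))

    raise InvalidInputError(f"unknown mesh kind {kind!r}")


# ---------------------------------------------------------------------------
# 2D chain -> 3D clipping path
# ---------------------------------------------------------------------------


def lift_chain(
    points2d,
    inside_side: int = 1,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    closed: bool = False,
) -> ClippingPath:
    """Lift a 2D polyline to a chain of plane widgets.

    Each segment becomes a widget whose plane contains the segment and the
    authoring plane's normal (an extrusion).  ``inside_side`` is +1 if the
    inside region lies to the left of the traversal direction, -1 for the
    right; widget normals point toward the opposite (outside) side.  For a
    closed chain the last point must not repeat the first; segments wrap.
    """
    pts = np.asarray(points2d, dtype=float).reshape(-1, 2)
    if inside_side not in (+1, -1):
        raise InvalidInputError("inside_side must be +1 (left) or -1 (right)")
    if closed:
        segs = list(zip(pts, np.vstack([pts[1:], pts[:1]])))
    else:
        segs = list(zip(pts[:-1], pts[1:]))
    if len(segs) < 1:
        raise InvalidInputError("need at least one segment")
    R = _CANON_ROT if rotation is None else np.asarray(rotation, dtype=float)
    t = _CANON_SHIFT if translation is None else np.asarray(translation, dtype=float)

    widgets = []
    for idx, (p, q) in enumerate(segs, start=1):
        d = q - p
        nd = np.linalg.norm(d)
        if nd <= 0:
            raise InvalidInputError("zero-length segment")
        d = d / nd
        # outward 2D normal: rotate the direction by -90deg for inside-left,
        # +90deg for inside-right
        if inside_side == +1:
            n2 = np.array([d[1], -d[0]])
        else:
            n2 = np.array([-d[1], d[0]])
        mid = 0.5 * (p + q)
        center = R @ np.array([mid[0], mid[1], 0.0]) + t
        normal = R @ np.array([n2[0], n2[1], 0.0])
        widgets.append(PlaneWidget(center=center, normal=normal, id=idx))
    return ClippingPath(widgets=tuple(widgets), closed=closed)


# ---------------------------------------------------------------------------
# figure-style chains (2D authoring coordinates)
# ---------------------------------------------------------------------------


def _convex_chain(n: int, span_deg: float = 140.0, radius: float = 10.0) -> np.ndarray:
    """n segments on a circular arc; chords of a convex fan."""
    if n < 1:
        raise InvalidInputError("need n >= 1")
    ang = np.deg2rad(np.linspace(90 + span_deg / 2, 90 - span_deg / 2, n + 1))
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


def _staircase_chain(n: int, turn_deg: float = 140.0, shrink: float = 0.4) -> np.ndarray:
    """Look-back fan: from the third edge on, every edge points directly away
    from the midpoint of the segment two places back, so the edge's backward
    extension crosses that segment — and that segment belongs to every
    head-chain the combination loop probes.  The loop therefore runs its
    maximum j−i−1 times in every composite call: the worst case.

    Edge lengths shrink geometrically; the fan slowly converges toward a
    self-similar direction, so consecutive edges approach parallel as n
    grows.  With the default parameters the consecutive-hinge margin stays
    two orders of magnitude above the parallelism tolerance for n ≤ 22,
    which covers the quadratic-law verification range.
    """
    if n < 1:
        raise InvalidInputError("need n >= 1")
    pts = [np.zeros(2), np.array([10.0, 0.0])]
    heading = np.deg2rad(turn_deg)
    length = 10.0 * shrink
    if n >= 2:
        pts.append(pts[-1] + length * np.array([np.cos(heading), np.sin(heading)]))
    for k in range(3, n + 1):
        q = 0.5 * (pts[k - 3] + pts[k - 2])
        d = pts[k - 1] - q
        d = d / np.linalg.norm(d)
        length *= shrink
        pts.append(pts[k - 1] + length * d)
    return np.asarray(pts)


# Worked-example chains (transection views of three 4-widget configurations).
# Coordinates are free; what is pinned down — and asserted by the tests via
# instrumentation — is which loop conditions fire and which inside tests
# hold, reproducing the reference decompositions.
_EXAMPLE1_PTS = np.array(
    [[0.0, 0.0], [10.0, 0.0], [12.0, 6.0], [7.0, 1.0], [3.0, -1.0]]
)
_EXAMPLE1_SIDE = -1

_EXAMPLE2_PTS = np.array(
    [[0.0, 0.0], [10.0, 0.0], [12.0, 6.0], [7.0, 1.0], [8.0, 3.0]]
)
_EXAMPLE2_SIDE = -1

_EXAMPLE3_PTS = np.array(
    [[0.0, 0.0], [10.0, 0.0], [12.0, 6.0], [7.0, 8.0], [9.0, 12.0]]
)
_EXAMPLE3_SIDE = -1


def gen_path(kind: str, params: dict | None = None, seed: int = 0):
    """Clipping-path fixtures.

    CONVEX (n): convex fan — best case, cost 2N−3, left-deep chain.
    STAIRCASE_WORST (n): spiral — worst case, cost (N+3)(N−2)/2+1.
    EXAMPLE1/2/3: the three worked 4-widget figures.
    ENCLOSURE (n=29, radius, center, height): closed prism loop around a
        target region, plus a thickness plane widget in params-out form.
    COMPLEX4 (radius): three sequential stages that cut a model spanning all
        regions into four parts; returns a list of (ClippingPath, keep_rule).
    """
    params = dict(params or {})

    if kind == "CONVEX":
        n = int(params.get("n", 4))
        pts = _convex_chain(n, float(params.get("span_deg", 140.0)))
        # inside on the outer (convex) side -> all-union left-deep chain
        return lift_chain(pts, inside_side=-1)

    if kind == "STAIRCASE_WORST":
        n = int(params.get("n", 4))
        pts = _staircase_chain(n)
        return lift_chain(pts, inside_side=-1)

    if kind == "EXAMPLE1":
        return lift_chain(_EXAMPLE1_PTS, inside_side=_EXAMPLE1_SIDE)
    if kind == "EXAMPLE2":
        return lift_chain(_EXAMPLE2_PTS, inside_side=_EXAMPLE2_SIDE)
    if kind == "EXAMPLE3":
        return lift_chain(_EXAMPLE3_PTS, inside_side=_EXAMPLE3_SIDE)

    if kind == "ENCLOSURE":
        n = int(params.get("n", 29))
        radius = float(params.get("radius", 0.55))
        cx, cy = params.get("center", (0.0, 0.0))
        if n < 3 or radius <= 0:
            raise InvalidInputError("enclosure needs n >= 3 and radius > 0")
        ang = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
        # CCW traversal, inside = interior = left side.  Authoring plane is
        # the xy-plane and the prism extrudes along z (identity lift) so the
        # enclosure drops straight onto meshes authored in model coordinates.
        return lift_chain(
            pts,
            inside_side=+1,
            rotation=np.eye(3),
            translation=np.zeros(3),
            closed=True,
        )

    if kind == "COMPLEX4":
        heights = params.get("heights", (-0.6, 0.0, 0.6))
        half = float(params.get("half_extent", 3.0))
        stages = []
        for h in heights:
            # authoring plane: model xz-plane (u=x, v=z), extrusion along -y;
            # a shallow 3-widget zigzag whose inside is the region below it
            pts = np.array(
                [
                    [-half, h - 0.25],
                    [-0.5, h],
                    [0.5, h + 0.02],
                    [half, h + 0.27],
                ]
            )
            rot = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
            stages.append(
                (lift_chain(pts, inside_side=-1, rotation=rot, translation=np.zeros(3)), "inside")
            )
        return stages

    raise InvalidInputError(f"unknown path kind {kind!r}")


# ---------------------------------------------------------------------------
# random chains and expressions
# ---------------------------------------------------------------------------


def _chain_simple(pts: np.ndarray, head: np.ndarray, tail: np.ndarray, tol: float) -> bool:
    """True iff the polyline *including its extension rays* is simple."""
    m = len(pts) - 1
    # core segments pairwise
    for i in range(m):
        for j in range(i + 2, m):
            if line_hits_polyline(
                pts[i], pts[i + 1], EntityKind.SEGMENT, Chain2D(points=pts[j : j + 2]), tol
            ):
                return False
    # head ray vs non-adjacent pieces
    head_chain = Chain2D(points=pts[1:], tail_dir=tail)  # segments 2..m + tail ray
    if line_hits_polyline(pts[0], pts[0] + head, EntityKind.RAY, head_chain, tol):
        return False
    if m >= 2:
        tail_chain = Chain2D(points=pts[: m - 1 + 1], head_dir=head)  # head + segments 1..m-1
        if line_hits_polyline(pts[-1], pts[-1] + tail, EntityKind.RAY, tail_chain, tol):
            return False
    return True


def gen_random_chain(n: int, seed: int = 0, max_tries: int = 500) -> ClippingPath:
    """Random valid non-self-intersecting open chain of ``n`` widgets.

    Turn angles are rejection-sampled in (−150°, 150°) (at least 10° in
    magnitude so consecutive hinges stay robust) and chains whose extended
    polyline self-intersects are rejected, so the even–odd side oracle is
    well defined.  Deterministic per seed.
    """
    if n < 2:
        raise InvalidInputError("need n >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        pts = [np.zeros(2)]
        heading = float(rng.uniform(0, 2 * np.pi))
        ok = True
        for i in range(n):
            d = np.array([np.cos(heading), np.sin(heading)])
            pts.append(pts[-1] + float(rng.uniform(0.5, 2.0)) * d)
            turn = float(rng.uniform(10.0, 150.0)) * (1 if rng.random() < 0.5 else -1)
            heading += np.deg2rad(turn)
        arr = np.asarray(pts)
        scale = float(np.linalg.norm(arr.max(0) - arr.min(0)))
        tol = 1e-9 * scale
        head = (arr[0] - arr[1]) / np.linalg.norm(arr[0] - arr[1])
        tail = (arr[-1] - arr[-2]) / np.linalg.norm(arr[-1] - arr[-2])
        if not _chain_simple(arr, head, tail, tol):
            ok = False
        if not ok:
            continue
        # random rigid placement in 3D
        angles = rng.uniform(0, 2 * np.pi, size=3)
        R = trimesh.transformations.euler_matrix(*angles)[:3, :3]
        t = rng.uniform(-5, 5, size=3)
        side = 1 if rng.random() < 0.5 else -1
        return lift_chain(arr, inside_side=side, rotation=R, translation=t)
    raise GenerationError(f"could not generate a simple chain of {n} widgets (seed {seed})")


def gen_random_expr(n_leaves: int, seed: int = 0, scale: float = 1.0) -> ImplicitExpr:
    """Random expression tree over random plane widgets — for clip stress
    tests; not a clipping-path combination."""
    if n_leaves < 1:
        raise InvalidInputError("need n_leaves >= 1")
    rng = np.random.default_rng(seed)

    def leaf(idx: int) -> ImplicitExpr:
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        center = rng.uniform(-scale, scale, size=3)
        return Leaf(PlaneWidget(center=center, normal=normal, id=idx))

    exprs = [leaf(i + 1) for i in range(n_leaves)]
    while len(exprs) > 1:
        i = int(rng.integers(len(exprs)))
        a = exprs.pop(i)
        j = int(rng.integers(len(exprs)))
        b = exprs.pop(j)
        op = Op.UNION if rng.random() < 0.5 else Op.INTERSECTION
        exprs.append(Node(op, a, b))
    return exprs[0]
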