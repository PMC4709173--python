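"""Reduction of a 3D clipping path to a 2D polyline and the recursive
Boolean-combination algorithm.

The chain of plane widgets α_1…α_N is transected by an auxiliary plane β
perpendicular to α_1 and α_2.  Each widget plane traces a line on β; the
hinge of consecutive widgets traces a vertex, so the whole path collapses to
a polyline P_1…P_{N+1} (extended by rays P′ beyond both endpoints).  All the
Boolean-operation decisions of the combination algorithm are 2D incidence
tests on that polyline:

* subproblem 1 — a single widget is its own implicit function;
* subproblem 2 — two adjacent widgets combine with ∩ if the far vertex
  P_{j+1} is inside α_i, else with ∪;
* subproblem 3 — a split index k is found by walking k from j downward while
  either (a) the infinite line through P_kP_{k+1} hits the head chain
  P′_i P_i … P_{k−1}, or (b) the ray from P_{k−1} through P_k hits the tail
  chain P_{k+2} … P_{j+1} P′_{j+1}; the two halves are then combined with
  ∩/∪ according to whether P_{k+1} is inside α_{k−1}.

The cost counter reproduces the recursion-cost metric T: every base-case
call and every composite call contributes 1, plus 1 per loop iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegeneratePathError,
    InvalidInputError,
    OrientationError,
    TransectionError,
)
from .implicit import (
    ImplicitExpr,
    Leaf,
    Node,
    Op,
    PlaneWidget,
    plane_value,
    reverse_widget,
)

__all__ = [
    "ClippingPath",
    "TransectionFrame",
    "TransectionPolyline",
    "CostCounter",
    "EntityKind",
    "Chain2D",
    "transection_frame",
    "transect",
    "orient_normals",
    "line_hits_polyline",
    "comb_imp_funs",
    "combine_path",
    "simulate_average_recurrence",
    "average_cost_closed_form",
    "best_case_cost",
    "worst_case_cost",
]

_PARALLEL_TOL = 1e-6  # consecutive-normal cross-product magnitude threshold


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClippingPath:
    """Ordered chain of connected plane widgets.

    ``closed`` marks enclosure-style paths whose last widget hinges back onto
    the first; ``reverse`` flips every normal before combination ("Reverse
    Clipping Path"), complementing the inside region.
    """

    widgets: tuple[PlaneWidget, ...]
    closed: bool = False
    reverse: bool = False

    def __post_init__(self):
        object.__setattr__(self, "widgets", tuple(self.widgets))
        if len(self.widgets) < 1:
            raise InvalidInputError("a clipping path needs at least one widget")

    def __len__(self) -> int:
        return len(self.widgets)

    def validate(self) -> None:
        """Enforce the pairwise-hinge invariant: consecutive planes must be
        non-parallel so they intersect in a line."""
        pairs = list(zip(self.widgets[:-1], self.widgets[1:]))
        if self.closed and len(self.widgets) >= 2:
            pairs.append((self.widgets[-1], self.widgets[0]))
        for a, b in pairs:
            if np.linalg.norm(np.cross(a.normal, b.normal)) <= _PARALLEL_TOL:
                raise DegeneratePathError(
                    f"widgets {a.id} and {b.id} are (near-)parallel: no hinge line"
                )


@dataclass(frozen=True)
class TransectionFrame:
    """Orthonormal right-handed frame {u, v, n_beta} spanning the plane β."""

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    n_beta: np.ndarray

    def to_2d(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        out = np.column_stack([p @ self.u, p @ self.v])
        return out[0] if np.asarray(points).ndim == 1 else out

    def to_3d(self, points2d) -> np.ndarray:
        q = np.atleast_2d(np.asarray(points2d, dtype=float))
        out = self.origin + q[:, :1] * self.u + q[:, 1:2] * self.v
        return out[0] if np.asarray(points2d).ndim == 1 else out


@dataclass(frozen=True)
class TransectionPolyline:
    """2D trace P_1…P_{N+1} of the widget chain on β.

    ``head_ray_dir``/``tail_ray_dir`` are the unit directions of the P′
    extensions beyond P_1 and P_{N+1}; ``inside_dirs[i]`` points from the
    midpoint of segment i toward widget i's inside region.
    """

    points: np.ndarray  # (N+1, 2)
    head_ray_dir: np.ndarray
    tail_ray_dir: np.ndarray
    inside_dirs: np.ndarray  # (N, 2)
    frame: TransectionFrame

    @property
    def n_segments(self) -> int:
        return len(self.points) - 1

    @property
    def scale(self) -> float:
        lo, hi = self.points.min(0), self.points.max(0)
        return max(float(np.linalg.norm(hi - lo)), 1e-300)

    @property
    def tol(self) -> float:
        """Geometric tolerance for all 2D predicates."""
        return 1e-9 * self.scale


@dataclass
class CostCounter:
    """Recursion-cost record T: one unit per call plus one per loop iteration.

    ``trace`` records one event per call for topology assertions:
    ("leaf", i), ("pair", i, j, op), or ("split", i, j, k, conditions, op)
    where ``conditions`` lists ("line"|"ray", k) per loop iteration.
    """

    base_calls: int = 0
    composite_calls: int = 0
    loop_iterations: int = 0
    trace: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.base_calls + self.composite_calls + self.loop_iterations

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "base_calls": self.base_calls,
            "composite_calls": self.composite_calls,
            "loop_iterations": self.loop_iterations,
        }


# ---------------------------------------------------------------------------
# 2D predicates
# ---------------------------------------------------------------------------


class EntityKind:
    SEGMENT = "segment"
    RAY = "ray"
    LINE = "line"


@dataclass(frozen=True)
class Chain2D:
    """A polyline with optional infinite extension rays at either end.

    Pieces are parametric: the head ray runs from ``points[0]`` along
    ``head_dir`` to infinity, segments join consecutive points, the tail ray
    runs from ``points[-1]`` along ``tail_dir``.
    """

    points: np.ndarray  # (m, 2), m >= 1
    head_dir: Optional[np.ndarray] = None
    tail_dir: Optional[np.ndarray] = None

    def pieces(self):
        """Yield (origin, direction, t_max) with t_max = inf for rays."""
        pts = self.points
        if self.head_dir is not None:
            yield pts[0], np.asarray(self.head_dir, float), np.inf
        for a, b in zip(pts[:-1], pts[1:]):
            yield a, b - a, 1.0
        if self.tail_dir is not None:
            yield pts[-1], np.asarray(self.tail_dir, float), np.inf

    def vertices(self) -> np.ndarray:
        return self.points


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def line_hits_polyline(
    a,
    b,
    kind: str,
    chain: Chain2D,
    tol: float,
) -> bool:
    """True iff the segment/ray/line through ``a``, ``b`` intersects the chain.

    The entity is the segment from a to b, the ray from a through b, or the
    infinite line through both, per ``kind``.  Intersections that land within
    ``tol`` of a chain vertex coinciding with one of the entity's defining
    points are excluded (shared-vertex rule); collinear overlap of positive
    length counts as an intersection.  An intersection parameter landing
    exactly on a range boundary (within ``tol``) raises a degeneracy warning
    and is treated as intersecting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b - a
    nd = np.linalg.norm(d)
    if nd <= tol:
        raise InvalidInputError("entity endpoints coincide")

    if kind == EntityKind.SEGMENT:
        s_lo, s_hi = 0.0, 1.0
    elif kind == EntityKind.RAY:
        s_lo, s_hi = 0.0, np.inf
    elif kind == EntityKind.LINE:
        s_lo, s_hi = -np.inf, np.inf
    else:
        raise InvalidInputError(f"unknown entity kind {kind!r}")

    # chain vertices coinciding with entity endpoints -> excluded points
    excluded = [
        v
        for v in chain.vertices()
        if min(np.linalg.norm(v - a), np.linalg.norm(v - b)) <= tol
    ]

    s_tol = tol / nd  # tolerance in entity-parameter units

    for origin, pdir, t_max in chain.pieces():
        npd = np.linalg.norm(pdir)
        if npd <= tol:
            continue
        denom = _cross2(d, pdir)
        rel = origin - a
        if abs(denom) <= tol * nd * npd / max(nd, npd):
            # parallel: collinear overlap of positive length counts
            if abs(_cross2(d, rel)) / nd > tol:
                continue  # parallel, offset: no contact
            # collinear: project the piece onto the entity parameter
            t0 = float(rel @ d) / (nd * nd)
            if np.isinf(t_max):
                t1 = np.inf if float(pdir @ d) > 0 else -np.inf
            else:
                t1 = t0 + float(pdir @ d) / (nd * nd)
            lo, hi = min(t0, t1), max(t0, t1)
            lo, hi = max(lo, s_lo), min(hi, s_hi)
            if hi - lo > s_tol:  # positive-length overlap
                return True
            continue
        s = _cross2(rel, pdir) / denom
        t = _cross2(rel, d) / denom
        t_tol = tol / npd
        in_s = (s_lo - s_tol) <= s <= (s_hi + s_tol if np.isfinite(s_hi) else np.inf)
        in_t = -t_tol <= t <= (t_max + t_tol if np.isfinite(t_max) else np.inf)
        if not (in_s and in_t):
            continue
        point = a + s * d
        if any(np.linalg.norm(point - e) <= tol for e in excluded):
            continue
        on_boundary = (
            abs(t) <= t_tol
            or (np.isfinite(t_max) and abs(t - t_max) <= t_tol)
            or (np.isfinite(s_lo) and abs(s - s_lo) <= s_tol)
            or (np.isfinite(s_hi) and abs(s - s_hi) <= s_tol)
        )
        if on_boundary:
            warnings.warn(
                "intersection at tolerance boundary; treated as intersecting",
                stacklevel=2,
            )
        return True
    return False


# ---------------------------------------------------------------------------
# transection
# ---------------------------------------------------------------------------


def transection_frame(path: ClippingPath) -> TransectionFrame:
    """Frame of the plane β perpendicular to the first two widget planes.

    ``n_beta`` is the normalised cross product of the first two normals; the
    origin is the point of the α_1–α_2 hinge line closest to widget 1's
    center, so coordinates on β stay well scaled.
    """
    if len(path) < 2:
        raise DegeneratePathError("transection needs at least two widgets")
    w1, w2 = path.widgets[0], path.widgets[1]
    nb = np.cross(w1.normal, w2.normal)
    nnb = np.linalg.norm(nb)
    if nnb <= _PARALLEL_TOL:
        raise DegeneratePathError("first two widget planes are (near-)parallel")
    nb = nb / nnb
    # hinge line: solve for a point on both planes, closest to w1.center
    A = np.vstack([w1.normal, w2.normal])
    rhs = np.array([w1.normal @ w1.center, w2.normal @ w2.center])
    p0, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    hinge_dir = nb  # the hinge line is parallel to n_beta
    p0 = p0 + ((w1.center - p0) @ hinge_dir) * hinge_dir
    u = w1.normal - (w1.normal @ nb) * nb
    u = u / np.linalg.norm(u)
    v = np.cross(nb, u)
    return TransectionFrame(origin=p0, u=u, v=v, n_beta=nb)


def _widget_line_2d(widget: PlaneWidget, frame: TransectionFrame):
    """Intersection of the widget plane with β as (gradient g, offset c):
    the plane function restricted to β is g·q + c for q in frame coords."""
    g = np.array([widget.normal @ frame.u, widget.normal @ frame.v])
    ng = np.linalg.norm(g)
    if ng <= _PARALLEL_TOL or abs(widget.normal @ frame.n_beta) >= 1.0 - 1e-9:
        raise TransectionError(
            f"widget {widget.id} plane is (near-)parallel to the transection plane"
        )
    c = float(widget.normal @ (frame.origin - widget.center))
    return g, c


def _line_intersect_2d(g1, c1, g2, c2, tol: float) -> np.ndarray:
    A = np.vstack([g1, g2])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) <= tol:
        raise DegeneratePathError("consecutive widget lines are parallel on beta")
    return np.linalg.solve(A, -np.array([c1, c2]))


def _endpoint_on_line(
    g: np.ndarray,
    c: float,
    hinge: np.ndarray,
    widget: PlaneWidget,
    frame: TransectionFrame,
    others: np.ndarray,
    distance: float,
) -> np.ndarray:
    """Free endpoint on the end widget's line, ``distance`` away from the
    hinge, on the side where the widget's own quad extends.

    The direction is taken from the projection of the widget center onto the
    line (the quad surrounds its center); if the center projects onto the
    hinge itself, fall back to the side opposite the remaining polyline.
    """
    # unit direction along the line {g.q + c = 0}
    d = np.array([-g[1], g[0]])
    d = d / np.linalg.norm(d)
    if widget.corners is not None:
        # free outer quad edge: the quad cuts β in a segment on this line;
        # take its endpoint farther from the hinge
        pts3 = widget.corners
        vals = (pts3 - frame.origin) @ frame.n_beta
        hits = []
        quad = np.vstack([pts3, pts3[:1]])
        for p, q, vp, vq in zip(quad[:-1], quad[1:], np.append(vals, vals[0])[:-1], np.append(vals, vals[0])[1:]):
            if (vp <= 0 <= vq) or (vq <= 0 <= vp):
                if vp != vq:
                    t = vp / (vp - vq)
                    hits.append(frame.to_2d(p + t * (q - p)))
        if len(hits) >= 2:
            hits = np.array(hits)
            far = hits[np.argmax(np.linalg.norm(hits - hinge, axis=1))]
            sign = np.sign(float((far - hinge) @ d))
            if sign != 0:
                return hinge + sign * distance * d
    cen = frame.to_2d(widget.center)
    along = float((cen - hinge) @ d)
    if abs(along) > 1e-12 * max(distance, 1.0):
        return hinge + np.sign(along) * distance * d
    if len(others):
        away = float((others.mean(0) - hinge) @ d)
        if abs(away) > 0:
            return hinge - np.sign(away) * distance * d
    return hinge + distance * d


def transect(path: ClippingPath, frame: TransectionFrame) -> TransectionPolyline:
    """Trace the widget chain on β as the polyline P_1…P_{N+1}."""
    widgets = path.widgets
    n = len(widgets)
    lines = [_widget_line_2d(w, frame) for w in widgets]

    # rough scale from line data to set the intersection tolerance
    tol0 = 1e-12

    hinges = []  # P_2 .. P_N
    for (g1, c1), (g2, c2) in zip(lines[:-1], lines[1:]):
        hinges.append(_line_intersect_2d(g1, c1, g2, c2, tol0))
    hinges = np.array(hinges).reshape(-1, 2)

    if hinges.size:
        diag = float(np.linalg.norm(hinges.max(0) - hinges.min(0)))
    else:
        diag = 0.0
    centers2d = np.array([frame.to_2d(w.center) for w in widgets])
    reach = 2.0 * max(
        (np.linalg.norm(centers2d - (hinges[0] if hinges.size else centers2d[0]), axis=1)).max(),
        1e-6,
    )
    distance = max(diag, reach, 1.0)

    if path.closed:
        if n < 3:
            raise DegeneratePathError("a closed path needs at least three widgets")
        gN, cN = lines[-1]
        g1, c1 = lines[0]
        p_close = _line_intersect_2d(gN, cN, g1, c1, tol0)
        points = np.vstack([p_close, hinges, p_close])
    else:
        if n == 1:
            g, c = lines[0]
            cen = frame.to_2d(widgets[0].center)
            d = np.array([-g[1], g[0]])
            d /= np.linalg.norm(d)
            foot = cen - (float(g @ cen) + c) / float(g @ g) * g
            points = np.vstack([foot - distance * d, foot + distance * d])
        else:
            p_first = _endpoint_on_line(
                *lines[0], hinges[0], widgets[0], frame, hinges[1:], distance
            )
            p_last = _endpoint_on_line(
                *lines[-1], hinges[-1], widgets[-1], frame, hinges[:-1], distance
            )
            points = np.vstack([p_first, hinges, p_last])

    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    scale = max(float(np.linalg.norm(points.max(0) - points.min(0))), 1e-300)
    if (seglen <= 1e-9 * scale).any():
        raise DegeneratePathError("transection produced coincident polyline points")

    head = (points[0] - points[1]) / np.linalg.norm(points[0] - points[1])
    tail = (points[-1] - points[-2]) / np.linalg.norm(points[-1] - points[-2])

    inside_dirs = []
    for g, _c in lines:
        d = -g / np.linalg.norm(g)  # toward decreasing plane value = inside
        inside_dirs.append(d)

    return TransectionPolyline(
        points=points,
        head_ray_dir=head,
        tail_ray_dir=tail,
        inside_dirs=np.array(inside_dirs),
        frame=frame,
    )


# ---------------------------------------------------------------------------
# normal orientation
# ---------------------------------------------------------------------------


def _segment_sides(polyline: TransectionPolyline) -> np.ndarray:
    """Local side (+1 left / -1 right of the traversal direction) on which
    each widget's inside witness lies."""
    pts = polyline.points
    sides = []
    for i in range(polyline.n_segments):
        d = pts[i + 1] - pts[i]
        s = _cross2(d, polyline.inside_dirs[i])
        sides.append(1 if s > 0 else -1 if s < 0 else 0)
    return np.array(sides)


def _core_is_simple(points: np.ndarray, closed: bool, tol: float) -> bool:
    """Check the hinge-to-hinge part of the polyline for self-intersection.

    For open paths the two end segments are exempt: their extents are
    artifacts of the free-endpoint placement and their crossings over the
    rest of the chain are legitimate geometry (it is exactly what the
    combination loop conditions probe on worst-case paths).  Adjacent
    segments sharing a vertex are always exempt; for closed paths the first
    and last segments count as adjacent."""
    m = len(points) - 1
    lo, hi = (0, m) if closed else (1, m - 1)
    for i in range(lo, hi):
        for j in range(i + 2, hi):
            if closed and i == 0 and j == m - 1:
                continue
            chain = Chain2D(points=points[j : j + 2])
            if line_hits_polyline(
                points[i], points[i + 1], EntityKind.SEGMENT, chain, tol
            ):
                return False
    return True


def orient_normals(path: ClippingPath, polyline: TransectionPolyline) -> ClippingPath:
    """Flip individual widget normals so every inside witness lies on one
    consistent side of the polyline.

    The side is the local side of the traversal direction, which coincides
    with the even–odd side of the extended polyline whenever the latter is
    simple; the majority side wins (ties go to widget 1), so a path that is
    already consistent is returned unchanged.
    """
    if len(path) <= 1:
        return path
    if not _core_is_simple(polyline.points, path.closed, polyline.tol):
        raise OrientationError(
            "polyline self-intersects: inside/outside sides are ill-defined"
        )
    sides = _segment_sides(polyline)
    if (sides == 0).any():
        raise OrientationError("degenerate inside direction on a segment")
    pos = int((sides > 0).sum())
    neg = len(sides) - pos
    ref = 1 if pos > neg else -1 if neg > pos else sides[0]
    if (sides == ref).all():
        return path
    new_widgets = [
        w if s == ref else reverse_widget(w) for w, s in zip(path.widgets, sides)
    ]
    return replace(path, widgets=tuple(new_widgets))


# ---------------------------------------------------------------------------
# the recursive Boolean-combination algorithm
# ---------------------------------------------------------------------------


def _inside(widget: PlaneWidget, point2d, polyline: TransectionPolyline) -> bool:
    """Is the 2D polyline point inside the widget's plane?  Strict sign test
    with the tie broken toward inside (→ intersection)."""
    p3 = polyline.frame.to_3d(np.asarray(point2d, float))
    return float(plane_value(widget, p3)) < polyline.tol


def _head_chain(polyline: TransectionPolyline, i: int, k: int) -> Chain2D:
    """Chain P′_i P_i … P_{k−1} (1-based indices; head ray extends segment
    P_iP_{i+1} beyond P_i)."""
    pts = polyline.points
    seg = pts[i - 1 : k - 1 + 1]  # P_i .. P_{k-1}
    head = pts[i - 1] - pts[i]
    head = head / np.linalg.norm(head)
    return Chain2D(points=seg, head_dir=head)


def _tail_chain(polyline: TransectionPolyline, k: int, j: int) -> Chain2D:
    """Chain P_{k+1} P_{k+2} … P_{j+1} P′_{j+1} (tail ray extends segment
    P_jP_{j+1} beyond P_{j+1}).

    This is the boundary the right subproblem (α_k…α_j) retains beyond the
    split hinge, which is what the extension of segment P_{k−1}P_k must be
    tested against; it starts one vertex before the hinge's far neighbour so
    the segment P_{k+1}P_{k+2} is included.  (The segment P_kP_{k+1} itself
    can only meet the tested ray at the shared point P_k, so its inclusion
    would be moot.)"""
    pts = polyline.points
    seg = pts[k : j + 1]  # P_{k+1} .. P_{j+1}
    tail = pts[j] - pts[j - 1]
    tail = tail / np.linalg.norm(tail)
    return Chain2D(points=seg, tail_dir=tail)


def comb_imp_funs(
    path: ClippingPath,
    polyline: TransectionPolyline,
    i: int,
    j: int,
    counter: CostCounter,
) -> ImplicitExpr:
    """Recursive Boolean combination of widgets α_i…α_j (1-based, inclusive).

    The path must already be consistently oriented (see
    :func:`orient_normals`).
    """
    n = len(path)
    if not (1 <= i <= j <= n):
        raise InvalidInputError(f"invalid index range ({i}, {j}) for N={n}")
    widgets = path.widgets
    pts = polyline.points
    tol = polyline.tol

    if i == j:
        counter.base_calls += 1
        counter.trace.append(("leaf", i))
        return Leaf(widgets[i - 1])

    if j - i == 1:
        counter.base_calls += 1
        op = Op.INTERSECTION if _inside(widgets[i - 1], pts[j], polyline) else Op.UNION
        counter.trace.append(("pair", i, j, op.value))
        return Node(op, Leaf(widgets[i - 1]), Leaf(widgets[j - 1]))

    counter.composite_calls += 1
    conditions = []
    k = j
    while k >= i + 2:
        # The entity is the boundary the right subproblem (α_k…α_j) would
        # gain at the split: segment P_kP_{k+1} extended beyond P_k — the
        # ray from P_{k+1} through P_k.  (Extending beyond P_{k+1} as well
        # would probe geometry that belongs to the right subchain itself and
        # misfires on meandering chains.)
        line_hit = line_hits_polyline(
            pts[k], pts[k - 1], EntityKind.RAY, _head_chain(polyline, i, k), tol
        )
        ray_hit = False
        if not line_hit and i + 2 <= k <= j - 1:
            ray_hit = line_hits_polyline(
                pts[k - 2], pts[k - 1], EntityKind.RAY, _tail_chain(polyline, k, j), tol
            )
        if not (line_hit or ray_hit):
            break
        conditions.append(("line" if line_hit else "ray", k))
        k -= 1
        counter.loop_iterations += 1

    op = (
        Op.INTERSECTION
        if _inside(widgets[k - 2], pts[k], polyline)
        else Op.UNION
    )
    counter.trace.append(("split", i, j, k, tuple(conditions), op.value))
    left = comb_imp_funs(path, polyline, i, k - 1, counter)
    right = comb_imp_funs(path, polyline, k, j, counter)
    return Node(op, left, right)


def combine_path(path: ClippingPath) -> tuple[ImplicitExpr, CostCounter]:
    """Top-level driver: frame → transect → orient → combine.

    Honors ``path.reverse`` by negating every widget normal before the
    combination, which complements the inside region exactly.
    """
    path.validate()
    if path.reverse:
        path = replace(
            path,
            widgets=tuple(reverse_widget(w) for w in path.widgets),
            reverse=False,
        )
    counter = CostCounter()
    if len(path) == 1:
        counter.base_calls += 1
        return Leaf(path.widgets[0]), counter
    frame = transection_frame(path)
    polyline = transect(path, frame)
    oriented = orient_normals(path, polyline)
    expr = comb_imp_funs(oriented, polyline, 1, len(path), counter)
    return expr, counter


# ---------------------------------------------------------------------------
# cost laws and the average-case recurrence simulator
# ---------------------------------------------------------------------------


def best_case_cost(n: int) -> int:
    """Closed form of the best-case (convex path) cost: 2N−3 for N ≥ 3."""
    if n <= 2:
        return 1
    return 2 * n - 3


def worst_case_cost(n: int) -> int:
    """Closed form of the worst-case (staircase path) cost:
    (N+3)(N−2)/2 + 1 for N ≥ 3."""
    if n <= 2:
        return 1
    return (n + 3) * (n - 2) // 2 + 1


def average_cost_closed_form(n: int) -> float:
    """Asymptotic average cost per widget, 1 + 2(ln N + 0.577 − 1)."""
    return 1.0 + 2.0 * (np.log(n) + 0.577 - 1.0)


def simulate_average_recurrence(n: int, reps: int, seed: int = 0) -> float:
    """Monte-Carlo mean of the average-case recursion cost per widget.

    Simulates the recurrence the average-case analysis solves: a problem of
    size 1 costs 1; a problem of size N ≥ 2 splits at a uniformly random
    position I ∈ {1,…,N−1} and costs N (the sub-chain scan) plus the costs of
    the two subproblems.  The expectation is exactly N(2·H_N − 1), so the
    returned mean-per-widget converges to 1 + 2(ln N + 0.577 − 1) as N and
    ``reps`` grow.

    Note this charges each composite call the full scan cost N, following the
    analysis's bookkeeping; the instrumented counter of the real algorithm
    (which charges only realised loop iterations, with T(1)=T(2)=1) is the
    exact measurement used for the best- and worst-case laws.
    """
    if n < 1 or reps < 1:
        raise InvalidInputError("need n >= 1 and reps >= 1")
    rng = np.random.default_rng(seed)
    totals = np.empty(reps, dtype=float)
    for r in range(reps):
        total = 0.0
        stack = [n]
        while stack:
            m = stack.pop()
            if m <= 1:
                total += 1.0
                continue
            total += m
            split = int(rng.integers(1, m))
            stack.append(split)
            stack.append(m - split)
        totals[r] = total
    return float(totals.mean()) / n
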