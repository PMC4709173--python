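"""Clipping triangle surface meshes by a combined implicit function.

The clip is a scalar-field split: every vertex gets the signed value of the
expression, triangles whose values straddle zero are cut by linear
interpolation on the sign-crossing edges, and the two halves are collected
into an *inside* mesh (values ≤ 0) and an *outside* mesh (values ≥ 0).  Cut
faces are left open — no capping — matching how clipped surgical models are
rendered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .errors import InvalidInputError, NumericError
from .implicit import ImplicitExpr, Leaf, Node, Op, PlaneWidget, eval_expr, reverse_widget
from .path import ClippingPath, combine_path

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "ClipResult",
    "clip_mesh",
    "apply_thickness",
    "sequential_clip",
    "connected_components",
]


@dataclass(frozen=True)
class TriangleMesh:
    """Indexed triangle surface: vertices (V,3) in model units (mm for the
    anatomy fixtures), faces (F,3) of 0-based vertex indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise InvalidInputError("face index out of range")
        if len(f) and (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise InvalidInputError("face references a vertex twice")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bbox_diagonal(self) -> float:
        if not len(self.vertices):
            return 0.0
        return float(
            np.linalg.norm(self.vertices.max(0) - self.vertices.min(0))
        )

    def area(self) -> float:
        if not len(self.faces):
            return 0.0
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriangleMesh":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))


@dataclass(frozen=True)
class ClipResult:
    """Two open halves of a clipped mesh plus the count of vertices created
    on the zero set."""

    inside: TriangleMesh
    outside: TriangleMesh
    cut_vertex_count: int


def _extract_submesh(
    vertices: np.ndarray, faces: list[tuple[int, int, int]]
) -> TriangleMesh:
    if not faces:
        return TriangleMesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
    f = np.asarray(faces, dtype=np.int64)
    used = np.unique(f)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(vertices=vertices[used], faces=remap[f])


def clip_mesh(mesh: TriangleMesh, expr: ImplicitExpr, eps: float | None = None) -> ClipResult:
    """Split ``mesh`` along the zero set of ``expr``.

    Vertices with value within ``eps`` of zero count as ON and are shared by
    both halves; mixed triangles are cut on their sign-crossing edges at the
    linear-interpolation parameter t = s_a / (s_a − s_b).  Total surface area
    is conserved exactly up to floating point.  ``eps`` defaults to
    1e-9 × the mesh bounding-box diagonal.
    """
    if mesh.n_faces == 0:
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        return ClipResult(inside=empty, outside=empty, cut_vertex_count=0)
    if eps is None:
        eps = 1e-9 * max(mesh.bbox_diagonal, 1e-30)
    s = np.asarray(eval_expr(expr, mesh.vertices), dtype=float)
    if not np.isfinite(s).all():
        raise NumericError("implicit function evaluated to a non-finite value")

    label = np.zeros(len(s), dtype=np.int8)  # -1 inside, 0 on, +1 outside
    label[s < -eps] = -1
    label[s > eps] = 1

    n0 = len(mesh.vertices)
    edge_cache: dict[tuple[int, int], int] = {}
    extra: list[np.ndarray] = []

    def cut(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = edge_cache.get(key)
        if idx is None:
            t = s[a] / (s[a] - s[b])
            p = mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a])
            idx = n0 + len(extra)
            extra.append(p)
            edge_cache[key] = idx
        return idx

    inside_faces: list[tuple[int, int, int]] = []
    outside_faces: list[tuple[int, int, int]] = []

    def emit_quad(faces, a, b, c, d):
        """Split quad a-b-c-d (in order) by its shorter diagonal."""

        def coord(i):
            return mesh.vertices[i] if i < n0 else extra[i - n0]

        if np.linalg.norm(coord(a) - coord(c)) <= np.linalg.norm(coord(b) - coord(d)):
            faces.append((a, b, c))
            faces.append((a, c, d))
        else:
            faces.append((a, b, d))
            faces.append((b, c, d))

    for tri in mesh.faces:
        lab = label[tri]
        if (lab <= 0).all():
            inside_faces.append(tuple(tri))
            continue
        if (lab >= 0).all():
            outside_faces.append(tuple(tri))
            continue
        # mixed: at least one strictly negative and one strictly positive
        neg = [v for v, l in zip(tri, lab) if l < 0]
        pos = [v for v, l in zip(tri, lab) if l > 0]
        on = [v for v, l in zip(tri, lab) if l == 0]
        if on:
            # one ON vertex, one neg, one pos: split through the ON vertex
            o, a, b = on[0], neg[0], pos[0]
            m = cut(a, b)
            # preserve original winding: find order of (o, a, b) in tri
            order = list(tri)
            if (order.index(a) - order.index(o)) % 3 == 1:
                inside_faces.append((o, a, m))
                outside_faces.append((o, m, b))
            else:
                inside_faces.append((o, m, a))
                outside_faces.append((o, b, m))
            continue
        if len(neg) == 1:
            # neg vertex isolated: triangle to inside, quad to outside
            a = neg[0]
            i0 = list(tri).index(a)
            b, c = tri[(i0 + 1) % 3], tri[(i0 + 2) % 3]  # both positive
            mab = cut(a, b)
            mca = cut(c, a)
            inside_faces.append((a, mab, mca))
            emit_quad(outside_faces, mab, b, c, mca)
        else:
            # pos vertex isolated: triangle to outside, quad to inside
            a = pos[0]
            i0 = list(tri).index(a)
            b, c = tri[(i0 + 1) % 3], tri[(i0 + 2) % 3]  # both negative
            mab = cut(a, b)
            mca = cut(c, a)
            outside_faces.append((a, mab, mca))
            emit_quad(inside_faces, mab, b, c, mca)

    all_vertices = np.vstack([mesh.vertices] + [np.asarray(extra)]) if extra else mesh.vertices
    inside = _extract_submesh(all_vertices, inside_faces)
    outside = _extract_submesh(all_vertices, outside_faces)
    return ClipResult(inside=inside, outside=outside, cut_vertex_count=len(extra))


def apply_thickness(
    path_expr: ImplicitExpr,
    thickness_widget: PlaneWidget,
    reverse_thickness: bool = False,
) -> ImplicitExpr:
    """Bound the clip on the thickness side: Boolean intersection of the
    path's implicit function with the thickness plane widget's, so the model
    is not cut through."""
    w = reverse_widget(thickness_widget) if reverse_thickness else thickness_widget
    return Node(Op.INTERSECTION, path_expr, Leaf(w))


def sequential_clip(
    mesh: TriangleMesh,
    stages: list[tuple[ClippingPath, str]],
) -> list[TriangleMesh]:
    """Clip ``mesh`` by a sequence of clipping paths.

    Each stage removes its path's inside region from the current remainder;
    the returned list holds every removed part followed by the final
    remainder.  The per-stage keep-rule is ``"inside"`` (default: the inside
    part is the removed piece) or ``"outside"`` (the roles swap).
    """
    if not stages:
        raise InvalidInputError("need at least one stage")
    remainder = mesh
    parts: list[TriangleMesh] = []
    for idx, (path, keep_rule) in enumerate(stages, start=1):
        expr, _ = combine_path(path)
        result = clip_mesh(remainder, expr)
        if keep_rule == "outside":
            removed, remainder = result.outside, result.inside
        else:
            removed, remainder = result.inside, result.outside
        if removed.n_faces == 0:
            warnings.warn(f"stage {idx}: inside region misses the remainder")
        parts.append(removed)
    parts.append(remainder)
    return parts


def connected_components(mesh: TriangleMesh) -> list[TriangleMesh]:
    """Partition the faces of ``mesh`` into vertex-connected components."""
    if mesh.n_faces == 0:
        return []
    f = mesh.faces
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    nv = mesh.n_vertices
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(nv, nv)
    )
    n_comp, vlabel = _cc(adj, directed=False)
    flabel = vlabel[f[:, 0]]
    out = []
    for c in range(n_comp):
        faces = f[flabel == c]
        if len(faces):
            out.append(_extract_submesh(mesh.vertices, [tuple(x) for x in faces]))
    return out
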