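"""File formats: mesh I/O (STL/OBJ/PLY via trimesh), the JSON clipping-path
schema (PathFileV1), fiducial CSV lists, and fiducial-to-path construction.

PathFileV1 schema::

    {
      "version": 1,
      "widgets": [{"center": [x,y,z], "normal": [x,y,z],
                   "corners": [[...]*4]?}, ...],
      "closed": false,
      "thickness_plane": {"center": [...], "normal": [...]}?,
      "reverse_path": false,
      "reverse_thickness": false
    }

Canonical formatting (sorted keys, fixed float repr) makes write→read→write
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

from .clip import TriangleMesh
from .errors import DegeneratePathError, InvalidInputError, MeshIOError
from .implicit import PlaneWidget
from .path import ClippingPath

logger = logging.getLogger(__name__)

__all__ = [
    "PathFile",
    "read_mesh",
    "write_mesh",
    "read_path",
    "write_path",
    "read_fiducials",
    "path_from_fiducials",
]

_MESH_FORMATS = {".stl", ".obj", ".ply"}


@dataclass
class PathFile:
    """In-memory form of a PathFileV1 document."""

    path: ClippingPath
    thickness_plane: Optional[PlaneWidget] = None
    reverse_thickness: bool = False

    @property
    def reverse_path(self) -> bool:
        return self.path.reverse


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def read_mesh(filename) -> TriangleMesh:
    p = Path(filename)
    if p.suffix.lower() not in _MESH_FORMATS:
        raise MeshIOError(f"unknown mesh extension {p.suffix!r} (use STL/OBJ/PLY)")
    if not p.exists():
        raise MeshIOError(f"no such file: {p}")
    try:
        m = trimesh.load_mesh(str(p), process=False)
    except Exception as exc:
        raise MeshIOError(f"malformed mesh file {p}: {exc}") from exc
    if isinstance(m, trimesh.Scene):
        geoms = list(m.geometry.values())
        if not geoms:
            raise MeshIOError(f"no geometry in {p}")
        m = trimesh.util.concatenate(geoms)
    # STL stores an unindexed triangle soup; re-weld exactly coincident
    # vertices so connectivity (components, shared edges) is recovered
    m.merge_vertices()
    try:
        mesh = TriangleMesh(np.asarray(m.vertices, float), np.asarray(m.faces))
    except InvalidInputError as exc:
        raise MeshIOError(f"invalid mesh in {p}: {exc}") from exc
    if mesh.n_faces == 0:
        raise MeshIOError(f"mesh file {p} contains no triangles")
    return mesh


def write_mesh(mesh: TriangleMesh, filename, file_format: Optional[str] = None) -> None:
    p = Path(filename)
    fmt = (file_format or p.suffix.lstrip(".")).lower()
    if f".{fmt}" not in _MESH_FORMATS:
        raise MeshIOError(f"unknown mesh format {fmt!r}")
    try:
        mesh.as_trimesh().export(str(p), file_type=fmt)
    except Exception as exc:
        raise MeshIOError(f"cannot write {p}: {exc}") from exc


# ---------------------------------------------------------------------------
# clipping-path JSON
# ---------------------------------------------------------------------------


def _widget_from_record(rec: dict, idx: int) -> PlaneWidget:
    if "center" not in rec or "normal" not in rec:
        raise MeshIOError(f"widget {idx}: missing center/normal")
    center = np.asarray(rec["center"], dtype=float)
    normal = np.asarray(rec["normal"], dtype=float)
    if center.shape != (3,) or normal.shape != (3,):
        raise MeshIOError(f"widget {idx}: center/normal must be 3-vectors")
    try:
        return PlaneWidget(
            center=center,
            normal=normal,
            id=idx,
            corners=np.asarray(rec["corners"], float) if rec.get("corners") else None,
        )
    except InvalidInputError as exc:
        raise MeshIOError(f"widget {idx}: {exc}") from exc


def read_path(filename) -> PathFile:
    p = Path(filename)
    if not p.exists():
        raise MeshIOError(f"no such file: {p}")
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise MeshIOError(f"malformed JSON in {p}: line {exc.lineno}: {exc.msg}") from exc
    if doc.get("version") != 1:
        raise MeshIOError(f"{p}: unsupported path file version {doc.get('version')!r}")
    widgets = doc.get("widgets")
    if not isinstance(widgets, list) or not widgets:
        raise MeshIOError(f"{p}: 'widgets' must be a non-empty list")
    path = ClippingPath(
        widgets=tuple(_widget_from_record(r, i + 1) for i, r in enumerate(widgets)),
        closed=bool(doc.get("closed", False)),
        reverse=bool(doc.get("reverse_path", False)),
    )
    path.validate()  # DegeneratePathError propagates: geometry, not I/O
    thickness = None
    if doc.get("thickness_plane") is not None:
        thickness = _widget_from_record(doc["thickness_plane"], 0)
    return PathFile(
        path=path,
        thickness_plane=thickness,
        reverse_thickness=bool(doc.get("reverse_thickness", False)),
    )


def _widget_record(w: PlaneWidget) -> dict:
    rec = {"center": [float(x) for x in w.center], "normal": [float(x) for x in w.normal]}
    if w.corners is not None:
        rec["corners"] = [[float(x) for x in c] for c in w.corners]
    return rec


def write_path(pf: PathFile, filename) -> None:
    doc = {
        "version": 1,
        "widgets": [_widget_record(w) for w in pf.path.widgets],
        "closed": bool(pf.path.closed),
        "reverse_path": bool(pf.path.reverse),
        "reverse_thickness": bool(pf.reverse_thickness),
        "thickness_plane": (
            _widget_record(pf.thickness_plane) if pf.thickness_plane is not None else None
        ),
    }
    Path(filename).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# fiducials
# ---------------------------------------------------------------------------


def read_fiducials(filename) -> np.ndarray:
    """CSV of x,y,z rows; '#' starts a comment.  Returns an (n, 3) array."""
    p = Path(filename)
    if not p.exists():
        raise MeshIOError(f"no such file: {p}")
    rows = []
    for ln, line in enumerate(p.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [s for s in line.replace(",", " ").split() if s]
        if len(parts) != 3:
            raise MeshIOError(f"{p}: row {ln}: expected 3 coordinates, got {len(parts)}")
        try:
            rows.append([float(s) for s in parts])
        except ValueError as exc:
            raise MeshIOError(f"{p}: row {ln}: {exc}") from exc
    pts = np.asarray(rows, dtype=float)
    if len(pts) < 2:
        raise MeshIOError(f"{p}: need at least 2 fiducial points")
    if not np.isfinite(pts).all():
        raise MeshIOError(f"{p}: non-finite coordinates")
    return pts


def path_from_fiducials(
    fiducials: np.ndarray,
    extrusion_dir,
    depth: float,
) -> ClippingPath:
    """Build a clipping path whose widget i is the quad through fiducials i
    and i+1 extruded along ``extrusion_dir`` by ``depth``.

    The widget normal is normalize(cross(f_{i+1} − f_i, extrusion_dir)); run
    the result through the orientation step before combining.
    """
    pts = np.asarray(fiducials, dtype=float).reshape(-1, 3)
    e = np.asarray(extrusion_dir, dtype=float).reshape(3)
    ne = np.linalg.norm(e)
    if ne == 0 or not np.isfinite(e).all():
        raise InvalidInputError("extrusion_dir must be a finite non-zero vector")
    e = e / ne
    if len(pts) < 2:
        raise InvalidInputError("need at least 2 fiducials")
    if depth <= 0:
        raise InvalidInputError("depth must be positive")
    widgets = []
    for i, (a, b) in enumerate(zip(pts[:-1], pts[1:]), start=1):
        d = b - a
        if np.linalg.norm(d) == 0:
            raise DegeneratePathError(f"fiducials {i} and {i+1} coincide")
        n = np.cross(d, e)
        nn = np.linalg.norm(n)
        if nn <= 1e-9 * np.linalg.norm(d):
            raise DegeneratePathError(
                f"fiducial segment {i} is parallel to the extrusion direction"
            )
        corners = np.array([a, b, b + depth * e, a + depth * e])
        widgets.append(
            PlaneWidget(
                center=corners.mean(axis=0), normal=n / nn, id=i, corners=corners
            )
        )
    path = ClippingPath(widgets=tuple(widgets))
    path.validate()
    return path
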