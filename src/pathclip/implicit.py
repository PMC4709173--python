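"""Signed implicit-function algebra over plane widgets.

A plane widget is a bounded planar quad with an oriented unit normal; it
contributes the linear implicit function

    F(p) = n . (p - c)

whose sign partitions space: F < 0 is the *inside* region (the side the
normal handle points away from), F = 0 the plane itself, F > 0 the outside.
Boolean union of implicit functions is the pointwise minimum, Boolean
intersection the pointwise maximum, so any binary tree over plane leaves is
again an implicit function and can be combined further.

Evaluation is vectorised: every entry point accepts a single 3D point or an
(M, 3) array of points.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from .errors import InvalidInputError, StructuralError

__all__ = [
    "PlaneWidget",
    "ImplicitExpr",
    "Leaf",
    "Node",
    "Op",
    "RegionLabel",
    "plane_value",
    "eval_expr",
    "classify",
    "reverse_widget",
    "expr_leaves",
    "expr_size",
    "expr_depth",
    "expr_to_text",
    "expr_to_json",
    "expr_from_json",
]

_UNIT_TOL = 1e-9
_PLANAR_TOL = 1e-6


class Op(enum.Enum):
    """Boolean operation on implicit functions."""

    UNION = "union"  # pointwise minimum
    INTERSECTION = "intersection"  # pointwise maximum

    @property
    def symbol(self) -> str:
        return "∪" if self is Op.UNION else "∩"

    @property
    def dual(self) -> "Op":
        return Op.INTERSECTION if self is Op.UNION else Op.UNION


class RegionLabel(enum.Enum):
    INSIDE = -1
    ON = 0
    OUTSIDE = 1


@dataclass(frozen=True)
class PlaneWidget:
    """A bounded planar quad with center, oriented unit normal and optional
    corner geometry.

    The normal points from the inside region toward the outside region;
    ``id`` is the 1-based index of the widget within its clipping path.
    """

    center: np.ndarray
    normal: np.ndarray
    id: int = 1
    corners: Optional[np.ndarray] = None

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float).reshape(3)
        normal = np.asarray(self.normal, dtype=float).reshape(3)
        if not (np.isfinite(center).all() and np.isfinite(normal).all()):
            raise InvalidInputError("widget center/normal must be finite")
        norm = float(np.linalg.norm(normal))
        if norm == 0.0:
            raise InvalidInputError(f"widget {self.id}: zero normal")
        if abs(norm - 1.0) > 1e-6:
            normal = normal / norm
        elif abs(norm - 1.0) > _UNIT_TOL:
            normal = normal / norm
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "normal", normal)
        if self.corners is not None:
            corners = np.asarray(self.corners, dtype=float).reshape(4, 3)
            if not np.isfinite(corners).all():
                raise InvalidInputError(f"widget {self.id}: non-finite corners")
            diag = float(np.linalg.norm(corners.max(0) - corners.min(0)))
            off = np.abs((corners - center) @ normal)
            if off.max() > _PLANAR_TOL * max(diag, 1.0):
                raise InvalidInputError(
                    f"widget {self.id}: corners are not coplanar with the widget plane"
                )
            # non-degenerate quad: consecutive edges must not vanish
            edges = np.diff(np.vstack([corners, corners[:1]]), axis=0)
            if np.linalg.norm(edges, axis=1).min() <= _PLANAR_TOL * max(diag, 1.0):
                raise InvalidInputError(f"widget {self.id}: degenerate quad")
            object.__setattr__(self, "corners", corners)

    def value(self, point) -> Union[float, np.ndarray]:
        return plane_value(self, point)


def plane_value(widget: PlaneWidget, point) -> Union[float, np.ndarray]:
    """Signed value of the widget's plane function at ``point``.

    Negative inside, zero on the plane, positive outside.  ``point`` may be
    a single 3-vector or an (M, 3) array.
    """
    p = np.asarray(point, dtype=float)
    if not np.isfinite(p).all():
        raise InvalidInputError("non-finite point coordinates")
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[-1] != 3:
        raise InvalidInputError(f"expected 3D point(s), got shape {p.shape}")
    v = (p - widget.center) @ widget.normal
    return float(v[0]) if scalar else v


def reverse_widget(widget: PlaneWidget) -> PlaneWidget:
    """Copy of ``widget`` with negated normal (inside/outside swapped)."""
    return replace(widget, normal=-widget.normal)


@dataclass(frozen=True)
class Leaf:
    widget: PlaneWidget

    def __str__(self) -> str:
        return f"a{self.widget.id}"


@dataclass(frozen=True)
class Node:
    op: Op
    left: "ImplicitExpr"
    right: "ImplicitExpr"

    def __str__(self) -> str:
        return expr_to_text(self)


ImplicitExpr = Union[Leaf, Node]


def _check_expr(expr: ImplicitExpr) -> None:
    if not isinstance(expr, (Leaf, Node)):
        raise StructuralError(f"not an implicit expression: {expr!r}")


def eval_expr(expr: ImplicitExpr, point) -> Union[float, np.ndarray]:
    """Evaluate the combined implicit function at one point or an (M,3) array.

    Union nodes take the pointwise minimum of their children, intersection
    nodes the pointwise maximum; leaves delegate to :func:`plane_value`.
    """
    _check_expr(expr)
    if isinstance(expr, Leaf):
        return plane_value(expr.widget, point)
    left = eval_expr(expr.left, point)
    right = eval_expr(expr.right, point)
    if expr.op is Op.UNION:
        return np.minimum(left, right) if isinstance(left, np.ndarray) else min(left, right)
    return np.maximum(left, right) if isinstance(left, np.ndarray) else max(left, right)


def classify(expr: ImplicitExpr, point, eps: Optional[float] = None) -> RegionLabel:
    """Trichotomy of a single point against the combined implicit function.

    ``eps`` defaults to 1e-9 * (1 + ||point||) so the ON band scales with the
    model's coordinate magnitude.
    """
    p = np.asarray(point, dtype=float).reshape(3)
    if eps is None:
        eps = 1e-9 * (1.0 + float(np.linalg.norm(p)))
    if eps <= 0:
        raise InvalidInputError("eps must be positive")
    v = eval_expr(expr, p)
    if abs(v) <= eps:
        return RegionLabel.ON
    return RegionLabel.INSIDE if v < 0 else RegionLabel.OUTSIDE


def expr_leaves(expr: ImplicitExpr) -> list[Leaf]:
    _check_expr(expr)
    if isinstance(expr, Leaf):
        return [expr]
    return expr_leaves(expr.left) + expr_leaves(expr.right)


def expr_size(expr: ImplicitExpr) -> tuple[int, int]:
    """(leaf count, internal node count) of the expression tree."""
    if isinstance(expr, Leaf):
        return 1, 0
    ll, ln = expr_size(expr.left)
    rl, rn = expr_size(expr.right)
    return ll + rl, ln + rn + 1


def expr_depth(expr: ImplicitExpr) -> int:
    if isinstance(expr, Leaf):
        return 0
    return 1 + max(expr_depth(expr.left), expr_depth(expr.right))


def expr_to_text(expr: ImplicitExpr) -> str:
    """Canonical infix text, e.g. ``(a1 ∪ (a2 ∩ a3))``."""
    _check_expr(expr)
    if isinstance(expr, Leaf):
        return f"a{expr.widget.id}"
    return f"({expr_to_text(expr.left)} {expr.op.symbol} {expr_to_text(expr.right)})"


def expr_to_json(expr: ImplicitExpr) -> Union[list, str]:
    """Nested-list JSON form: ["union", ["plane", 1], ["plane", 2]] etc."""
    _check_expr(expr)
    if isinstance(expr, Leaf):
        return ["plane", expr.widget.id]
    return [expr.op.value, expr_to_json(expr.left), expr_to_json(expr.right)]


def expr_from_json(obj, widgets: dict[int, PlaneWidget]) -> ImplicitExpr:
    """Rebuild an expression from its nested-list form.

    ``widgets`` maps 1-based widget ids to the leaves' plane widgets.
    """
    if isinstance(obj, str):
        obj = json.loads(obj)
    if not isinstance(obj, (list, tuple)) or len(obj) < 2:
        raise StructuralError(f"malformed expression node: {obj!r}")
    tag = obj[0]
    if tag == "plane":
        wid = int(obj[1])
        if wid not in widgets:
            raise StructuralError(f"unknown widget id {wid}")
        return Leaf(widgets[wid])
    if tag in (Op.UNION.value, Op.INTERSECTION.value):
        if len(obj) != 3:
            raise StructuralError(f"operation node needs two children: {obj!r}")
        return Node(Op(tag), expr_from_json(obj[1], widgets), expr_from_json(obj[2], widgets))
    raise StructuralError(f"unknown expression tag {tag!r}")
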