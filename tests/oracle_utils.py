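"""Independent 2D side oracle used by the tests.

Membership in the region bounded by an extended polyline (core segments plus
the two infinite end rays) is decided by crossing parity of a finite
connecting path between the query point and a reference point of known side.
This is exact for any simple curve, bounded or not, and shares no code with
the recursive combination algorithm it checks.
"""

from __future__ import annotations

import numpy as np


def make_pieces(polyline):
    """Parametric pieces (origin, direction, t_max) of the extended polyline."""
    pts = polyline.points
    pieces = [(pts[0], polyline.head_ray_dir, np.inf)]
    for a, b in zip(pts[:-1], pts[1:]):
        pieces.append((a, b - a, 1.0))
    pieces.append((pts[-1], polyline.tail_ray_dir, np.inf))
    return pieces


def seg_crossings(a, b, pieces, tol):
    """Number of crossings of segment ab with the pieces; None if the segment
    passes within tol of a piece endpoint or runs collinear (degenerate)."""
    d = b - a
    nd = np.linalg.norm(d)
    if nd < tol:
        return None
    n = 0
    for o, pdir, tmax in pieces:
        npd = np.linalg.norm(pdir)
        den = d[0] * pdir[1] - d[1] * pdir[0]
        rel = o - a
        if abs(den) < 1e-12 * nd * npd:
            if abs(rel[0] * d[1] - rel[1] * d[0]) / nd < tol:
                return None
            continue
        s = (rel[0] * pdir[1] - rel[1] * pdir[0]) / den
        t = (rel[0] * d[1] - rel[1] * d[0]) / den
        s_tol = tol / nd
        t_tol = tol / npd
        hi = tmax + t_tol if np.isfinite(tmax) else np.inf
        if -s_tol < s < 1 + s_tol and -t_tol < t < hi:
            near = (
                abs(s) < s_tol
                or abs(s - 1) < s_tol
                or abs(t) < t_tol
                or (np.isfinite(tmax) and abs(t - tmax) < t_tol)
            )
            if near:
                return None
            n += 1
    return n


def same_side(q, ref, pieces, scale, rng):
    """True iff q and ref lie in the same component of the complement."""
    tol = 1e-9 * scale
    direct = seg_crossings(q, ref, pieces, tol)
    if direct is not None:
        return direct % 2 == 0
    for _ in range(64):
        w = 0.5 * (q + ref) + rng.normal(size=2) * scale
        c1 = seg_crossings(q, w, pieces, tol)
        c2 = seg_crossings(w, ref, pieces, tol)
        if c1 is not None and c2 is not None:
            return (c1 + c2) % 2 == 0
    raise RuntimeError("no robust connecting path found")


def check_chain_against_oracle(path, n_points=400, seed=0, margin=0.5):
    """Classify sample points with the combined expression and with the side
    oracle; return (mismatches, total points compared)."""
    from pathclip import combine_path, eval_expr, orient_normals, transect, transection_frame

    rng = np.random.default_rng(seed)
    frame = transection_frame(path)
    oriented = orient_normals(path, transect(path, frame))
    polyline = transect(oriented, frame)
    expr, _ = combine_path(path)

    pts = polyline.points
    pieces = make_pieces(polyline)
    scale = polyline.scale
    witnesses = [
        0.5 * (pts[i] + pts[i + 1]) + 1e-4 * scale * polyline.inside_dirs[i]
        for i in range(polyline.n_segments)
    ]
    ref = witnesses[0]
    assert all(same_side(w, ref, pieces, scale, rng) for w in witnesses[1:]), (
        "inside witnesses are not on one side: invalid chain"
    )
    lo, hi = pts.min(0), pts.max(0)
    span = hi - lo
    qs = rng.uniform(lo - margin * span, hi + margin * span, size=(n_points, 2))
    vals = np.asarray(eval_expr(expr, polyline.frame.to_3d(qs)))
    keep = np.abs(vals) > 10 * polyline.tol
    mism = sum(
        1
        for q, v in zip(qs[keep], vals[keep])
        if same_side(q, ref, pieces, scale, rng) != (v < 0)
    )
    return mism, int(keep.sum())
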