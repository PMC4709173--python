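"""Transection, orientation, intersection predicates, the recursive
combination, its cost laws, and the recurrence simulator."""

import numpy as np
import pytest
from shapely.geometry import LineString

from pathclip import (
    Chain2D,
    ClippingPath,
    DegeneratePathError,
    EntityKind,
    Leaf,
    PlaneWidget,
    average_cost_closed_form,
    best_case_cost,
    combine_path,
    eval_expr,
    expr_size,
    expr_to_text,
    gen_path,
    gen_random_chain,
    line_hits_polyline,
    lift_chain,
    orient_normals,
    simulate_average_recurrence,
    transect,
    transection_frame,
    worst_case_cost,
)
from pathclip.implicit import reverse_widget

from oracle_utils import check_chain_against_oracle


def _two_orthogonal_widgets():
    w1 = PlaneWidget(center=(1, 0, 0), normal=(0, 1, 0), id=1)
    w2 = PlaneWidget(center=(0, 1, 0), normal=(1, 0, 0), id=2)
    return ClippingPath(widgets=(w1, w2))


class TestTransectionFrame:
    def test_normal_is_cross_product(self):
        frame = transection_frame(_two_orthogonal_widgets())
        np.testing.assert_allclose(frame.n_beta, (0, 0, -1), atol=1e-12)

    def test_frame_perpendicular_to_both_widgets(self):
        path = gen_random_chain(5, seed=3)
        frame = transection_frame(path)
        for w in path.widgets[:2]:
            assert abs(frame.n_beta @ w.normal) < 1e-9
        # right-handed orthonormal
        np.testing.assert_allclose(np.cross(frame.u, frame.v), frame.n_beta, atol=1e-9)

    def test_near_parallel_first_widgets_rejected(self):
        w1 = PlaneWidget(center=(0, 0, 0), normal=(1, 0, 0), id=1)
        w2 = PlaneWidget(center=(1, 0, 0), normal=(1, 1e-9, 0), id=2)
        with pytest.raises(DegeneratePathError):
            transection_frame(ClippingPath(widgets=(w1, w2)))


class TestTransect:
    def test_right_angle_l_shape(self):
        path = _two_orthogonal_widgets()
        frame = transection_frame(path)
        poly = transect(path, frame)
        assert poly.points.shape == (3, 2)
        a, b, c = poly.points
        v1, v2 = a - b, c - b
        cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert cosang == pytest.approx(0.0, abs=1e-9)  # 90 degree corner

    def test_segments_lie_on_widget_planes(self):
        path = gen_random_chain(6, seed=9)
        frame = transection_frame(path)
        poly = transect(path, frame)
        assert poly.points.shape == (7, 2)
        for i, w in enumerate(path.widgets):
            for q in (poly.points[i], poly.points[i + 1]):
                assert abs(float(w.value(frame.to_3d(q)))) < 1e-6 * poly.scale

    def test_example_polyline_has_five_points(self):
        path = gen_path("EXAMPLE1")
        poly = transect(path, transection_frame(path))
        assert poly.points.shape == (5, 2)

    def test_ray_directions_extend_end_segments(self):
        path = gen_random_chain(4, seed=1)
        poly = transect(path, transection_frame(path))
        p = poly.points
        np.testing.assert_allclose(
            poly.head_ray_dir, (p[0] - p[1]) / np.linalg.norm(p[0] - p[1])
        )
        np.testing.assert_allclose(
            poly.tail_ray_dir, (p[-1] - p[-2]) / np.linalg.norm(p[-1] - p[-2])
        )


class TestOrientNormals:
    def test_consistent_path_unchanged(self):
        path = gen_path("CONVEX", {"n": 5})
        frame = transection_frame(path)
        poly = transect(path, frame)
        assert orient_normals(path, poly) is path

    def test_single_flipped_widget_restored(self):
        path = gen_path("CONVEX", {"n": 5})
        widgets = list(path.widgets)
        widgets[2] = reverse_widget(widgets[2])
        flipped = ClippingPath(widgets=tuple(widgets))
        frame = transection_frame(flipped)
        poly = transect(flipped, frame)
        fixed = orient_normals(flipped, poly)
        for a, b in zip(fixed.widgets, path.widgets):
            np.testing.assert_allclose(a.normal, b.normal, atol=1e-12)

    def test_single_widget_path_unchanged(self):
        w = PlaneWidget(center=(0, 0, 0), normal=(0, 0, 1), id=1)
        path = ClippingPath(widgets=(w,))
        assert orient_normals(path, None) is path


class TestLineHitsPolyline:
    def test_crossing_line(self):
        chain = Chain2D(points=np.array([[-1.0, -1.0], [-1.0, 1.0]]))
        assert line_hits_polyline((0, 0), (1, 0), EntityKind.LINE, chain, 1e-9)

    def test_ray_does_not_reach_behind_origin(self):
        chain = Chain2D(points=np.array([[-2.0, -1.0], [-2.0, 1.0]]))
        assert not line_hits_polyline((0, 0), (1, 0), EntityKind.RAY, chain, 1e-9)
        assert line_hits_polyline((0, 0), (1, 0), EntityKind.LINE, chain, 1e-9)

    def test_single_point_chain_is_never_hit(self):
        chain = Chain2D(points=np.array([[5.0, 5.0]]))
        assert not line_hits_polyline((0, 0), (1, 0), EntityKind.LINE, chain, 1e-9)

    def test_collinear_overlap_counts(self):
        chain = Chain2D(points=np.array([[2.0, 0.0], [5.0, 0.0]]))
        assert line_hits_polyline((0, 0), (3, 0), EntityKind.SEGMENT, chain, 1e-9)
        # collinear but disjoint: no contact
        assert not line_hits_polyline((0, 0), (1, 0), EntityKind.SEGMENT, chain, 1e-9)

    def test_segment_predicate_matches_shapely(self):
        """Brute-force cross-check of the segment/segment case."""
        rng = np.random.default_rng(42)
        agree = 0
        for _ in range(300):
            a, b = rng.uniform(-1, 1, size=(2, 2))
            pts = rng.uniform(-1, 1, size=(3, 2))
            chain = Chain2D(points=pts)
            got = line_hits_polyline(a, b, EntityKind.SEGMENT, chain, 1e-12)
            want = LineString([a, b]).intersects(LineString(pts))
            # skip near-degenerate configurations where the tolerance rules
            # legitimately differ from shapely's exact predicate
            d = LineString([a, b]).distance(LineString(pts))
            if 1e-9 < d or (got and want):
                assert got == want
                agree += 1
        assert agree > 250

    def test_hit_near_shared_vertex_excluded(self):
        # entity endpoint coincides with a chain vertex; contact there only
        chain = Chain2D(points=np.array([[1.0, 0.0], [2.0, 1.0]]))
        assert not line_hits_polyline((1, 0), (0, 1), EntityKind.SEGMENT, chain, 1e-9)


class TestWorkedExamples:
    """The three 4-widget worked examples: reference expressions and traces."""

    def test_example1_value_equals_reference_form(self):
        """The produced tree is the associativity-rebracketed form of the
        reference right-deep expression; the implicit functions are identical."""
        path = gen_path("EXAMPLE1")
        expr, counter = combine_path(path)
        assert expr_to_text(expr) == "((a1 ∪ a2) ∪ (a3 ∩ a4))"
        # pointwise equality with the right-deep form a1∪(a2∪(a3∩a4))
        from pathclip.implicit import Node, Op

        w = {leaf.widget.id: leaf.widget for leaf in _leaves(expr)}
        reference = Node(
            Op.UNION,
            Leaf(w[1]),
            Node(Op.UNION, Leaf(w[2]), Node(Op.INTERSECTION, Leaf(w[3]), Leaf(w[4]))),
        )
        rng = np.random.default_rng(0)
        pts = rng.uniform(-30, 30, size=(500, 3))
        np.testing.assert_array_equal(
            np.asarray(eval_expr(expr, pts)), np.asarray(eval_expr(reference, pts))
        )

    @pytest.mark.parametrize("name", ["EXAMPLE2", "EXAMPLE3"])
    def test_examples_2_and_3_match_reference_expression(self, name):
        expr, counter = combine_path(gen_path(name))
        assert expr_to_text(expr) == "(a1 ∪ ((a2 ∪ a3) ∩ a4))"
        # decision topology: the loop fires twice at the top level, then the
        # sub-chain splits off its last widget with an intersection
        splits = [ev for ev in counter.trace if ev[0] == "split"]
        assert splits[0][1:4] == (1, 4, 2) and len(splits[0][4]) == 2
        assert splits[1][1:4] == (2, 4, 4) and splits[1][5] == "intersection"



def _leaves(expr):
    from pathclip import expr_leaves

    return expr_leaves(expr)


class TestCostLaws:
    def test_base_cases_cost_one(self):
        w = PlaneWidget(center=(0, 0, 0), normal=(0, 0, 1), id=1)
        expr, c = combine_path(ClippingPath(widgets=(w,)))
        assert isinstance(expr, Leaf) and c.total == 1
        expr, c = combine_path(gen_path("CONVEX", {"n": 2}))
        assert c.total == 1

    @pytest.mark.parametrize("n", [3, 7, 15, 30])
    def test_convex_best_case(self, n):
        expr, c = combine_path(gen_path("CONVEX", {"n": n}))
        assert c.total == best_case_cost(n) == 2 * n - 3
        leaves, internal = expr_size(expr)
        assert leaves == n and internal == n - 1
        from pathclip import expr_depth

        assert expr_depth(expr) == n - 1  # left-deep chain

    @pytest.mark.parametrize("n", [4, 9, 20])
    def test_staircase_worst_case(self, n):
        _, c = combine_path(gen_path("STAIRCASE_WORST", {"n": n}))
        assert c.total == worst_case_cost(n) == (n + 3) * (n - 2) // 2 + 1

    def test_counter_identity(self):
        _, c = combine_path(gen_path("STAIRCASE_WORST", {"n": 8}))
        assert c.total == c.base_calls + c.composite_calls + c.loop_iterations


class TestCombinedExpressionInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_expression_size(self, seed):
        n = 3 + seed
        expr, _ = combine_path(gen_random_chain(n, seed=seed))
        leaves, internal = expr_size(expr)
        assert leaves == n and internal == n - 1

    def test_reversal_complements_classification(self):
        from dataclasses import replace

        path = gen_random_chain(6, seed=21)
        expr, _ = combine_path(path)
        rexpr, _ = combine_path(replace(path, reverse=True))
        rng = np.random.default_rng(0)
        pts = rng.uniform(-10, 10, size=(500, 3))
        v = np.asarray(eval_expr(expr, pts))
        rv = np.asarray(eval_expr(rexpr, pts))
        np.testing.assert_allclose(rv, -v, atol=1e-9)


class TestOracleEquivalence:
    """Combined-expression signs against the 2D side oracle."""

    @pytest.mark.parametrize("trial", range(25))
    def test_random_chain_classification(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(3, 13))
        path = gen_random_chain(n, seed=7000 + trial)
        mism, total = check_chain_against_oracle(path, n_points=300, seed=trial)
        assert mism == 0
        assert total > 200

    def test_closed_enclosure_against_point_in_polygon(self):
        """Closed paths are guarded by a polygon-containment oracle."""
        from shapely.geometry import Point, Polygon

        n, radius = 12, 0.7
        path = gen_path("ENCLOSURE", {"n": n, "radius": radius})
        expr, _ = combine_path(path)
        ang = 2 * np.pi * np.arange(n) / n
        poly = Polygon(np.column_stack([radius * np.cos(ang), radius * np.sin(ang)]))
        rng = np.random.default_rng(4)
        pts = rng.uniform(-1.2, 1.2, size=(800, 2))
        pts3 = np.column_stack([pts, rng.uniform(-1, 1, size=800)])
        vals = np.asarray(eval_expr(expr, pts3))
        for (x, y), v in zip(pts, vals):
            d = poly.exterior.distance(Point(x, y))
            if d < 1e-6:
                continue
            assert (v < 0) == poly.contains(Point(x, y))


class TestRecurrenceSimulator:
    def test_small_sizes_exact(self):
        assert simulate_average_recurrence(1, reps=5) == pytest.approx(1.0)
        # size 2 is a composite call in the analyzed recurrence: cost 2+1+1
        assert simulate_average_recurrence(2, reps=5) == pytest.approx(2.0)
        # size 3: both splits give 3 + T(1) + T(2) = 8, mean/N = 8/3
        assert simulate_average_recurrence(3, reps=20, seed=1) == pytest.approx(8 / 3)

    def test_exact_expectation_is_harmonic(self):
        """E[T(N)]/N = 2*H_N - 1 for the analyzed recurrence."""
        for n in (10, 50):
            h = (1.0 / np.arange(1, n + 1)).sum()
            got = simulate_average_recurrence(n, reps=4000, seed=42)
            assert got == pytest.approx(2 * h - 1, rel=0.02)

    def test_converges_to_logarithmic_closed_form(self):
        n = 1000
        got = simulate_average_recurrence(n, reps=200, seed=42)
        assert got == pytest.approx(average_cost_closed_form(n), rel=0.05)

    def test_bad_arguments(self):
        from pathclip import InvalidInputError

        with pytest.raises(InvalidInputError):
            simulate_average_recurrence(0, reps=1)


class TestDegenerateInputs:
    def test_parallel_consecutive_widgets_rejected(self):
        w1 = PlaneWidget(center=(0, 0, 0), normal=(0, 0, 1), id=1)
        w2 = PlaneWidget(center=(0, 0, 1), normal=(0, 0, 1), id=2)
        with pytest.raises(DegeneratePathError):
            combine_path(ClippingPath(widgets=(w1, w2)))

    def test_self_intersecting_interior_rejected(self):
        # hinge-to-hinge segments P2P3 and P4P5 cross
        pts = np.array(
            [[0, 0], [4, 0], [6, 2], [2, 4], [5, -1], [8, 1], [10, 0.0]]
        )
        path = lift_chain(pts, inside_side=1)
        from pathclip import OrientationError

        with pytest.raises(OrientationError):
            combine_path(path)
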