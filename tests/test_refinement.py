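"""Importance fields, subdivision levels, tessellation, Hermite evaluation."""

import numpy as np
import pytest

from neurotess.mesh_quality_io import is_closed_manifold
from neurotess.refinement import (
    RefineConfig,
    audit_crack_freeness,
    edge_outer_level,
    hermite_center,
    importance_from_camera,
    refine_mesh,
    subdivision_levels,
    tessellate_patch,
    uniform_importance,
)


class TestImportance:
    def test_point_at_camera_gets_max_level(self, small_tracing):
        pid = small_tracing.neurite_roots[0]
        cam = small_tracing.points[pid].position
        imp = importance_from_camera(small_tracing, cam, 6, 5.0, 50.0)
        assert imp[pid] == 6.0

    def test_all_points_beyond_far_get_level_one(self, small_tracing):
        imp = importance_from_camera(small_tracing, (1e5, 0, 0), 6, 5.0, 50.0)
        assert set(imp.values()) == {1.0}

    def test_monotone_nonincreasing_in_distance(self, small_tracing):
        cam = np.zeros(3)
        imp = importance_from_camera(small_tracing, cam, 8, 3.0, 120.0)
        items = [
            (np.linalg.norm(p.position - cam), imp[pid])
            for pid, p in small_tracing.points.items()
        ]
        items.sort()
        for (d1, i1), (d2, i2) in zip(items, items[1:]):
            assert i1 >= i2 - 1e-12

    def test_near_geq_far_rejected(self, small_tracing):
        with pytest.raises(ValueError):
            importance_from_camera(small_tracing, (0, 0, 0), 4, 50.0, 50.0)


class TestSubdivisionLevels:
    CFG = RefineConfig()

    def test_constant_field_gives_constant_levels(self):
        spec = subdivision_levels([10, 11, 12, 13], [4, 4, 4, 4], self.CFG)
        assert spec.outer == (4, 4, 4, 4)
        assert spec.inner == (4, 4)

    def test_mean_weighting_rounds_half_up(self):
        lvl = edge_outer_level(1, 2, 2.0, 4.0, self.CFG)
        assert lvl == 3
        lvl = edge_outer_level(1, 2, 2.0, 3.0, self.CFG)  # 2.5 rounds up
        assert lvl == 3

    def test_levels_clamped_to_range(self):
        cfg = RefineConfig(max_level=5)
        assert edge_outer_level(1, 2, 40.0, 40.0, cfg) == 5

    def test_shared_edge_levels_agree_between_patches(self, rng):
        cfg = RefineConfig(outer_weight=0.3)  # asymmetric weights
        for _ in range(1000):
            imp_a, imp_b = rng.uniform(1, 9, size=2)
            # the same physical edge seen from two patches in opposite order
            assert edge_outer_level(7, 12, imp_a, imp_b, cfg) == edge_outer_level(
                12, 7, imp_b, imp_a, cfg
            )


class TestTessellatePatch:
    def test_identity_levels_return_original_quad(self):
        pts, tris = tessellate_patch([1, 1, 1, 1], [1, 1])
        assert len(pts) == 4
        assert len(tris) == 2

    def test_uniform_level_two_gives_3x3_grid(self):
        pts, tris = tessellate_patch([2, 2, 2, 2], [2, 2])
        assert len(pts) == 9
        assert len(tris) == 8
        area = 0.0
        for t in tris:
            a, b, c = pts[t]
            area += 0.5 * abs(
                (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            )
        assert area == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "outer,inner",
        [
            ((1, 3, 1, 3), (1, 1)),
            ((2, 5, 4, 3), (3, 3)),
            ((1, 1, 1, 1), (4, 4)),
            ((6, 2, 3, 5), (2, 2)),
        ],
    )
    def test_mixed_levels_cover_unit_square(self, outer, inner):
        pts, tris = tessellate_patch(outer, inner)
        # no duplicate parametric coords
        assert len({tuple(p) for p in pts}) == len(pts)
        area = 0.0
        for t in tris:
            a, b, c = pts[t]
            area += 0.5 * abs(
                (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            )
        assert area == pytest.approx(1.0, abs=1e-12)
        # every boundary vertex lies on the square's boundary and vice versa
        on_boundary = [
            p for p in pts if 0.0 in (p[0], p[1]) or 1.0 in (p[0], p[1])
        ]
        o0, o1, o2, o3 = outer
        assert len(on_boundary) == 4 + (o0 - 1) + (o1 - 1) + (o2 - 1) + (o3 - 1)


class TestHermiteCenter:
    def test_endpoints_exact(self, rng):
        t0, t1 = rng.normal(size=3), rng.normal(size=3)
        o0, o1 = rng.normal(size=3), rng.normal(size=3)
        o0, o1 = o0 / np.linalg.norm(o0), o1 / np.linalg.norm(o1)
        assert np.abs(hermite_center(t0, o0, t1, o1, 0.0) - t0).max() < 1e-12
        assert np.abs(hermite_center(t0, o0, t1, o1, 1.0) - t1).max() < 1e-12

    def test_collinear_unit_tangent_midpoint(self):
        # straight unit segment with aligned tangents stays on the segment
        t0, t1 = np.zeros(3), np.array([1.0, 0, 0])
        o = np.array([1.0, 0, 0])
        c = hermite_center(t0, o, t1, o, 0.5, tangent_scale=1.0)
        assert np.allclose(c, [0.5, 0, 0], atol=1e-15)

    def test_matches_direct_polynomial_evaluation(self, rng):
        t0, t1 = rng.normal(size=3), rng.normal(size=3)
        o0, o1 = rng.normal(size=3), rng.normal(size=3)
        y = 0.37
        s = np.linalg.norm(t1 - t0)
        expected = (
            (2 * y**3 - 3 * y**2 + 1) * t0
            + (y**3 - 2 * y**2 + y) * s * o0
            + (y**3 - y**2) * s * o1
            + (-2 * y**3 + 3 * y**2) * t1
        )
        assert np.allclose(hermite_center(t0, o0, t1, o1, y), expected, atol=1e-13)

    def test_vectorised_y_matches_scalar(self, rng):
        t0, t1, o0, o1 = (rng.normal(size=3) for _ in range(4))
        ys = rng.random(16)
        batch = hermite_center(t0, o0, t1, o1, ys)
        for y, row in zip(ys, batch):
            assert np.array_equal(row, hermite_center(t0, o0, t1, o1, float(y)))

    def test_adaptive_tangents_keep_longitudinal_speed_positive(self, rng):
        """Loop suppression: with length-scaled tangents the centerline never
        stalls or reverses for randomised orientation pairs, while fixed
        oversized tangents do exhibit stalls (the loop artifact class)."""
        n_trials = 2000
        y = np.linspace(0.0, 1.0, 33)
        h = y[1] - y[0]

        def min_speed(t0, o0, t1, o1, scale_mode):
            if scale_mode == "adaptive":
                c = hermite_center(t0, o0, t1, o1, y, tangent_scale=1.0)
            else:  # fixed large tangent magnitude, ignoring segment length
                big = 8.0 / max(np.linalg.norm(t1 - t0), 1e-9)
                c = hermite_center(t0, o0, t1, o1, y, tangent_scale=big)
            d = np.diff(c, axis=0) / h
            fwd = d @ (t1 - t0)
            return fwd.min()

        adaptive_fail = fixed_fail = 0
        for _ in range(n_trials):
            t0 = rng.normal(size=3)
            t1 = t0 + rng.normal(size=3)
            o0, o1 = rng.normal(size=3), rng.normal(size=3)
            o0 /= np.linalg.norm(o0)
            o1 /= np.linalg.norm(o1)
            # orientation vectors never oppose the travel direction by more
            # than 90 degrees (they bisect adjacent segments)
            d01 = t1 - t0
            if o0 @ d01 < 0:
                o0 = -o0
            if o1 @ d01 < 0:
                o1 = -o1
            if min_speed(t0, o0, t1, o1, "adaptive") <= 0:
                adaptive_fail += 1
            if min_speed(t0, o0, t1, o1, "fixed") <= 0:
                fixed_fail += 1
        assert adaptive_fail == 0
        assert fixed_fail > 0


class TestRefineMesh:
    def test_uniform_importance_one_is_identity(self, small_coarse, small_tracing):
        refined = refine_mesh(small_coarse, uniform_importance(small_tracing, 1))
        assert len(refined.vertices) == len(small_coarse.vertices)
        assert np.array_equal(refined.vertices, small_coarse.vertices)
        assert len(refined.triangles) == 2 * len(small_coarse.faces)

    @pytest.mark.parametrize("level", [2, 3, 4])
    def test_uniform_refinement_matches_grid_census(
        self, straight_tube_coarse, straight_tube_tracing, level
    ):
        refined = refine_mesh(
            straight_tube_coarse, uniform_importance(straight_tube_tracing, level)
        )
        v0 = len(straight_tube_coarse.vertices)
        f0 = len(straight_tube_coarse.faces)
        e0 = 2 * f0  # closed all-quad mesh
        assert len(refined.vertices) == v0 + (level - 1) * e0 + (level - 1) ** 2 * f0
        assert len(refined.triangles) == 2 * level**2 * f0

    def test_refined_mesh_closed_manifold(self, small_coarse, small_tracing):
        refined = refine_mesh(small_coarse, uniform_importance(small_tracing, 3))
        rep = is_closed_manifold(refined.as_mesh())
        assert rep.is_closed and rep.is_manifold
        assert rep.euler_characteristic == 2
        assert rep.n_components == 1

    def test_monotone_triangle_cost_in_level(self, small_coarse, small_tracing):
        counts = [
            len(
                refine_mesh(
                    small_coarse, uniform_importance(small_tracing, lvl)
                ).triangles
            )
            for lvl in (1, 2, 3, 4, 5)
        ]
        assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_camera_field_gives_closed_crack_free_mesh(
        self, small_coarse, small_tracing
    ):
        cam = small_tracing.points[small_tracing.neurite_roots[0]].position
        imp = importance_from_camera(small_tracing, cam, 6, 10.0, 60.0)
        cfg = RefineConfig(max_level=6)
        refined = refine_mesh(small_coarse, imp, cfg)
        rep = is_closed_manifold(refined.as_mesh())
        assert rep.is_closed and rep.is_manifold and rep.euler_characteristic == 2
        assert audit_crack_freeness(small_coarse, imp, cfg) == 0.0

    def test_straight_tube_refines_to_exact_cylinder(
        self, straight_tube_coarse, straight_tube_tracing
    ):
        """Constant radius + straight axis: every refined tube vertex must lie
        exactly one radius from the x axis."""
        refined = refine_mesh(
            straight_tube_coarse, uniform_importance(straight_tube_tracing, 4)
        )
        tube_x_min = 5.0  # neurite spans x in [5, 25]
        sel = [
            i
            for i, (fi, _, _) in enumerate(refined.provenance)
            if fi >= 0 and straight_tube_coarse.face_kinds[fi] == "lateral"
        ]
        pts = refined.vertices[sel]
        pts = pts[pts[:, 0] > tube_x_min + 1e-9]  # on the tube proper
        r_axis = np.sqrt(pts[:, 1] ** 2 + pts[:, 2] ** 2)
        assert np.abs(r_axis - 1.0).max() < 1e-12

    def test_displacement_radius_identity(self, small_coarse, small_tracing):
        """|v - c| = r for every Hermite-evaluated vertex."""
        from neurotess.refinement import _patch_data

        refined = refine_mesh(small_coarse, uniform_importance(small_tracing, 3))
        checked = 0
        for i, (fi, x, y) in enumerate(refined.provenance):
            if fi < 0 or x < 0:
                continue
            if small_coarse.face_kinds[fi] != "lateral":
                continue
            pd = _patch_data(small_coarse, fi)
            c = hermite_center(pd.t0, pd.o0, pd.t1, pd.o1, y)
            r = (1 - y) * pd.r0 + y * pd.r1
            assert abs(np.linalg.norm(refined.vertices[i] - c) - r) < 1e-12
            checked += 1
        assert checked > 100

    def test_importance_below_one_rejected(self, small_coarse, small_tracing):
        imp = uniform_importance(small_tracing, 2)
        imp[next(iter(imp))] = 0.5
        with pytest.raises(ValueError):
            refine_mesh(small_coarse, imp)


class TestCrackFreeness:
    def test_zero_gap_for_random_importance_fields(
        self, small_coarse, small_tracing, rng
    ):
        ids = list(small_tracing.points) + [
            sp.id for sp in small_tracing.soma_points
        ]
        cfg = RefineConfig(max_level=8)
        for _ in range(50):
            imp = {pid: float(rng.integers(1, 9)) for pid in ids}
            assert audit_crack_freeness(small_coarse, imp, cfg) == 0.0

    def test_refined_closed_for_random_importance_fields(
        self, small_coarse, small_tracing, rng
    ):
        ids = list(small_tracing.points) + [
            sp.id for sp in small_tracing.soma_points
        ]
        cfg = RefineConfig(max_level=6)
        for _ in range(10):
            imp = {pid: float(rng.integers(1, 7)) for pid in ids}
            refined = refine_mesh(small_coarse, imp, cfg)
            rep = is_closed_manifold(refined.as_mesh())
            assert rep.is_closed and rep.is_manifold
            assert rep.euler_characteristic == 2
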