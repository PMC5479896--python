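"""Tetrahedral icosphere, quad pairing, anchor selection, elastic soma."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from neurotess.mesh_quality_io import Mesh, is_closed_manifold, mesh_volume
from neurotess.soma_fem import (
    ElasticParams,
    NeuriteAnchor,
    build_tet_icosphere,
    deform_soma,
    pair_triangles_to_quads,
    poisson_sweep,
    select_neurite_quads,
    solve_dirichlet,
    _exhaustive_matching,
    _planarity_score,
    _tet_volumes,
    _unit_icosphere_surface,
)


class TestIcosphere:
    def test_level0_counts_and_euler(self):
        ico = build_tet_icosphere((0, 0, 0), 1.0, 0)
        assert len(ico.vertices) == 13  # 12 surface + centre
        assert len(ico.tetrahedra) == 20
        assert len(ico.surface_triangles) == 20
        v = ico.n_surface_vertices
        e = len(
            {
                tuple(sorted((t[i], t[(i + 1) % 3])))
                for t in ico.surface_triangles
                for i in range(3)
            }
        )
        assert v - e + len(ico.surface_triangles) == 2

    def test_all_tets_positive_volume(self):
        for level in (0, 1, 2):
            ico = build_tet_icosphere((1, -2, 0.5), 3.0, level)
            assert np.all(_tet_volumes(ico.vertices, ico.tetrahedra) > 0)

    def test_surface_vertices_on_sphere_at_offset_center(self):
        center = np.array([1.0, 2.0, 3.0])
        ico = build_tet_icosphere(center, 2.5, 0)
        surf = np.unique(ico.surface_triangles)
        d = np.linalg.norm(ico.vertices[surf] - center, axis=1)
        assert np.allclose(d, 2.5, atol=1e-9)

    def test_volume_converges_monotonically_to_sphere(self):
        r = 2.0
        exact = 4.0 / 3.0 * np.pi * r**3
        errs = []
        for level in range(4):
            ico = build_tet_icosphere((0, 0, 0), r, level)
            vol = float(_tet_volumes(ico.vertices, ico.tetrahedra).sum())
            errs.append(abs(vol - exact) / exact)
            assert vol < exact  # inscribed polyhedron
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_surface_closed_after_pairing(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 1.0, 1))
        rep = is_closed_manifold(Mesh(ico.vertices, [list(q) for q in ico.surface_quads]))
        assert rep.is_closed and rep.is_manifold
        assert rep.euler_characteristic == 2

    def test_tet_interior_conforms(self):
        # every internal triangular face shared by exactly 2 tets,
        # boundary faces by exactly 1 (conforming decomposition)
        ico = build_tet_icosphere((0, 0, 0), 1.0, 2)
        faces = {}
        for tet in ico.tetrahedra:
            for f in ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]):
                key = tuple(sorted(tet[list(f)]))
                faces[key] = faces.get(key, 0) + 1
        counts = np.array(list(faces.values()))
        assert set(counts) <= {1, 2}
        n_boundary = int((counts == 1).sum())
        assert n_boundary == len(ico.surface_triangles)


class TestQuadPairing:
    def test_icosahedron_pairs_into_10_quads(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 1.0, 0))
        assert len(ico.surface_quads) == 10
        used = [t for pair in ico.quad_triangle_pairs for t in pair]
        assert sorted(used) == list(range(20))

    def test_matching_score_equals_brute_force_optimum(self):
        # blossom result must achieve the exhaustive-search optimum at level 0
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 1.0, 0))
        sf = ico.surface_triangles
        unit_v, _ = _unit_icosphere_surface(0)
        edge_to_tris = {}
        for ti, tri in enumerate(sf):
            for i in range(3):
                e = tuple(sorted((int(tri[i]), int(tri[(i + 1) % 3]))))
                edge_to_tris.setdefault(e, []).append(ti)
        adj = sorted(tuple(sorted(t)) for t in edge_to_tris.values() if len(t) == 2)
        scores = [_planarity_score(unit_v, sf[a], sf[b]) for a, b in adj]
        brute = _exhaustive_matching(adj, scores, 20)
        smap = dict(zip(adj, scores))
        got = sum(smap[tuple(sorted(p))] for p in map(tuple, ico.quad_triangle_pairs))
        best = sum(smap[tuple(sorted(p))] for p in brute)
        assert got == pytest.approx(best, abs=1e-12)

    def test_vertex_count_unchanged_by_pairing(self):
        ico = build_tet_icosphere((0, 0, 0), 1.0, 1)
        before = ico.n_surface_vertices
        pair_triangles_to_quads(ico)
        assert int(np.unique(ico.surface_quads).size) == before

    def test_quad_areas_equal_source_triangle_areas(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 1.0, 1))

        def tri_area(pts):
            return 0.5 * np.linalg.norm(
                np.cross(pts[1] - pts[0], pts[2] - pts[0])
            )

        tri_total = sum(tri_area(ico.vertices[t]) for t in ico.surface_triangles)
        quad_total = 0.0
        for q in ico.surface_quads:
            p = ico.vertices[q]
            # quad cycle starts on the shared diagonal: fan at corner 0
            quad_total += tri_area(p[[0, 1, 2]]) + tri_area(p[[0, 2, 3]])
        assert quad_total == pytest.approx(tri_total, rel=1e-12)


class TestAnchorSelection:
    def test_anchor_along_quad_centroid_gets_that_quad(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 2.0, 1))
        target = 7
        centroid = ico.vertices[ico.surface_quads[target]].mean(axis=0)
        anc = [NeuriteAnchor(1, 3.0 * centroid, 0.3)]
        select_neurite_quads(ico, anc)
        assert anc[0].assigned_quad == target

    def test_empty_anchor_list_is_noop(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 2.0, 0))
        assert select_neurite_quads(ico, []) == []

    def test_opposite_anchors_get_distinct_disjoint_quads(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 2.0, 0))
        anc = [
            NeuriteAnchor(1, (3.0, 0.1, 0.0), 0.3),
            NeuriteAnchor(2, (-3.0, -0.1, 0.0), 0.3),
        ]
        select_neurite_quads(ico, anc)
        qa, qb = anc[0].assigned_quad, anc[1].assigned_quad
        assert qa != qb
        assert not set(ico.surface_quads[qa]) & set(ico.surface_quads[qb])

    def test_two_anchor_assignment_is_globally_optimal(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 2.0, 0))
        dirs = [np.array([1.0, 0.2, -0.1]), np.array([-0.3, 1.0, 0.4])]
        anc = [NeuriteAnchor(i, 3 * d, 0.2) for i, d in enumerate(dirs)]
        select_neurite_quads(ico, anc)
        quads = ico.surface_quads
        cent = ico.vertices[quads].mean(axis=1)
        cdir = cent / np.linalg.norm(cent, axis=1, keepdims=True)

        def cost(i, q):
            d = dirs[i] / np.linalg.norm(dirs[i])
            return np.arccos(np.clip(cdir[q] @ d, -1, 1))

        got = cost(0, anc[0].assigned_quad) + cost(1, anc[1].assigned_quad)
        best = min(
            cost(0, qa) + cost(1, qb)
            for qa in range(len(quads))
            for qb in range(len(quads))
            if qa != qb and not set(quads[qa]) & set(quads[qb])
        )
        assert got == pytest.approx(best, abs=1e-12)

    def test_more_anchors_than_quads_rejected(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 2.0, 0))
        anc = [NeuriteAnchor(i, (3.0, i, 0), 0.1) for i in range(11)]
        with pytest.raises(ValueError):
            select_neurite_quads(ico, anc)


class TestElasticDeformation:
    def test_no_anchors_is_identity(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 2.0, 1))
        deformed, amap = deform_soma(ico, [])
        assert np.array_equal(deformed, ico.vertices)
        assert amap == {}

    def test_rigid_translation_of_all_surface_vertices(self):
        ico = build_tet_icosphere((0, 0, 0), 2.0, 1)
        surf = np.unique(ico.surface_triangles)
        d = np.array([0.7, -0.3, 1.1])
        out = solve_dirichlet(ico, surf, ico.vertices[surf] + d)
        assert np.abs(out - (ico.vertices + d)).max() < 1e-9

    def test_linear_patch_test_affine_field_reproduced(self):
        ico = build_tet_icosphere((0, 0, 0), 2.0, 1)
        surf = np.unique(ico.surface_triangles)
        a = np.array([[1.1, 0.2, 0.0], [0.0, 0.9, 0.1], [0.05, 0.0, 1.05]])
        b = np.array([0.3, -0.2, 0.5])
        target_all = ico.vertices @ a.T + b
        out = solve_dirichlet(ico, surf, target_all[surf])
        assert np.abs(out - target_all).max() < 1e-8

    def test_youngs_modulus_invariance_under_dirichlet(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 5.0, 1))
        anc = [NeuriteAnchor(1, (6.0, 0.5, 0.2), 0.8)]
        select_neurite_quads(ico, anc)
        d1, _ = deform_soma(ico, anc, ElasticParams(poisson=0.3, young=1.0))
        d2, _ = deform_soma(ico, anc, ElasticParams(poisson=0.3, young=10.0))
        assert np.abs(d1 - d2).max() < 1e-10

    def test_mirror_symmetric_anchors_give_mirror_symmetric_soma(self):
        # mirror the domain and the pull targets about x = 0: the elastic
        # equilibrium must be the mirror image of the original one
        import dataclasses

        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 5.0, 1))
        mirror = np.array([-1.0, 1.0, 1.0])
        tets_m = ico.tetrahedra[:, [0, 2, 1, 3]]  # restore orientation
        ico_m = dataclasses.replace(
            ico, vertices=ico.vertices * mirror, tetrahedra=tets_m
        )
        quad = ico.surface_quads[3]
        centroid = ico.vertices[quad].mean(axis=0)
        d = centroid / np.linalg.norm(centroid)
        targets = centroid + 1.2 * d + 0.4 * (ico.vertices[quad] - centroid)
        sol = solve_dirichlet(ico, quad, targets)
        sol_m = solve_dirichlet(ico_m, quad, targets * mirror)
        assert np.abs(sol_m - sol * mirror).max() < 1e-8

    def test_deformed_surface_stays_closed_manifold(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 5.0, 1))
        anc = [
            NeuriteAnchor(1, (6.0, 0.5, 0.2), 0.8),
            NeuriteAnchor(2, (0.1, -6.0, 0.4), 0.5),
        ]
        select_neurite_quads(ico, anc)
        deformed, _ = deform_soma(ico, anc)
        rep = is_closed_manifold(Mesh(deformed, [list(q) for q in ico.surface_quads]))
        assert rep.is_closed and rep.is_manifold and rep.euler_characteristic == 2

    def test_invalid_poisson_rejected(self):
        with pytest.raises(ValueError):
            ElasticParams(poisson=0.5)
        with pytest.raises(ValueError):
            ElasticParams(poisson=-1.0)


@pytest.fixture(scope="module")
def anchored():
    ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 5.0, 1))
    anc = [
        NeuriteAnchor(1, (6.0, 0.5, 0.2), 0.8),
        NeuriteAnchor(2, (-0.3, 6.0, -0.5), 0.6),
        NeuriteAnchor(3, (0.2, -0.4, -6.0), 0.7),
    ]
    select_neurite_quads(ico, anc)
    return ico, anc


class TestPoissonSweep:
    def test_single_value_gives_single_pair(self, anchored):
        ico, anc = anchored
        out = poisson_sweep(ico, anc, [0.3])
        assert len(out) == 1 and out[0][0] == 0.3

    def test_volume_nonincreasing_in_poisson_ratio(self, anchored):
        # lower Poisson's ratio -> more swelling -> larger volume
        ico, anc = anchored
        out = poisson_sweep(ico, anc, [0.0, 0.15, 0.3, 0.45])
        vols = [v for _, v in out]
        assert all(a >= b - 1e-9 for a, b in zip(vols, vols[1:]))
        assert vols[0] > vols[-1]  # strict somewhere: the trend is real

    def test_no_anchors_volume_constant(self):
        ico = pair_triangles_to_quads(build_tet_icosphere((0, 0, 0), 5.0, 1))
        out = poisson_sweep(ico, [], [0.1, 0.3])
        assert out[0][1] == pytest.approx(out[1][1], rel=1e-12)

    def test_unsorted_nu_rejected(self, anchored):
        ico, anc = anchored
        with pytest.raises(ValueError):
            poisson_sweep(ico, anc, [0.3, 0.1])
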