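"""Contact module: octree, segment distances, detection and forces."""

import numpy as np
import pytest

from conftest import random_rod

from aneucoil.contact import (
    ContactSet,
    FrictionParams,
    Octree,
    WallSurface,
    broad_phase_radius,
    candidate_pairs_coil,
    coil_coil_friction,
    coil_coil_normal_force,
    detect_coil_collisions,
    detect_wall_collisions,
    min_distance_segments,
    wall_friction,
    wall_normal_force,
)
from aneucoil.rod import make_rod_state


def brute_force_candidates(vertices, D2):
    """O(N^2) oracle for the broad-phase necessary condition."""
    centers = 0.5 * (vertices[:-1] + vertices[1:])
    lbar = np.mean(np.linalg.norm(np.diff(vertices, axis=0), axis=1))
    rad = np.sqrt((lbar / 2) ** 2 + D2**2)
    out = set()
    for i in range(len(centers)):
        for j in range(i + 2, len(centers)):
            if np.linalg.norm(centers[j] - centers[i]) <= rad:
                out.add((i, j))
    return out


def sampled_segment_distance(p1, q1, p2, q2, n=400):
    """Dense-sampling distance oracle on an n x n parameter grid."""
    s = np.linspace(0, 1, n)[:, None]
    a = p1 + s * (q1 - p1)
    b = p2 + s * (q2 - p2)
    d2 = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2 * a @ b.T
    )
    return np.sqrt(max(d2.min(), 0.0))


class TestOctree:
    def test_every_item_indexed_once(self, rng):
        pts = rng.normal(0, 1, (500, 3))
        ot = Octree(pts)
        items = np.concatenate(ot.leaf_item_lists())
        assert sorted(items) == list(range(500))

    def test_query_superset(self, rng):
        pts = rng.normal(0, 1, (300, 3))
        ot = Octree(pts)
        for _ in range(50):
            q = rng.normal(0, 1, 3)
            r = rng.uniform(0.05, 2.0)
            got = set(ot.query(q, r))
            true = set(np.flatnonzero(np.linalg.norm(pts - q, axis=1) <= r))
            assert true <= got

    def test_duplicate_points_capacity_overflow(self):
        pts = np.zeros((40, 3))
        ot = Octree(pts, leaf_capacity=8, max_depth=5)
        assert sorted(np.concatenate(ot.leaf_item_lists())) == list(range(40))

    def test_near_linear_build_scaling(self, rng):
        # soft check, logged only: doubling N should not blow up the
        # leaf count superlinearly
        n1 = Octree(rng.normal(0, 1, (500, 3))).n_leaves
        n2 = Octree(rng.normal(0, 1, (1000, 3))).n_leaves
        assert n2 < 4 * n1


class TestSegmentDistance:
    def test_parallel_offset(self):
        d, vec, _ = min_distance_segments(
            [0, 0, 0], [1, 0, 0], [0, 0, 0.7], [1, 0, 0.7]
        )
        assert np.isclose(d, 0.7)

    def test_crossing_perpendicular(self):
        d, _, _ = min_distance_segments(
            [-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0]
        )
        assert d < 1e-12

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            min_distance_segments([0, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_direction_vector_consistent(self):
        d, vec, (s, t) = min_distance_segments(
            [0, 0, 0], [1, 0, 0], [2, 1, 0], [3, 1, 0]
        )
        # closest points: (1,0,0) and (2,1,0); vec points 1 -> 2
        assert np.isclose(d, np.sqrt(2))
        assert np.allclose(vec, [1, 1, 0])
        assert (s, t) == (1.0, 0.0)

    def test_matches_sampling_oracle(self, rng):
        for _ in range(200):
            p1, q1, p2, q2 = rng.normal(0, 1, (4, 3))
            if min(np.linalg.norm(q1 - p1), np.linalg.norm(q2 - p2)) < 1e-6:
                continue
            d, _, _ = min_distance_segments(p1, q1, p2, q2)
            ref = sampled_segment_distance(p1, q1, p2, q2)
            assert d <= ref + 1e-12
            assert abs(d - ref) < 1e-3 * max(1.0, ref)


class TestDetection:
    def test_candidates_match_brute_force(self):
        D2 = 0.3
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 200))
            pts = np.cumsum(rng.normal(0, 0.25, (n, 3)), axis=0)
            st = make_rod_state(pts)
            got = {tuple(p) for p in candidate_pairs_coil(st, D2=D2)}
            assert got == brute_force_candidates(pts, D2)

    def test_far_pairs_not_returned_and_adjacent_excluded(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [30, 0, 0], [31, 0, 0]], dtype=float)
        st = make_rod_state(pts)
        pairs = candidate_pairs_coil(st, D2=0.3)
        assert len(pairs) == 0

    def test_collision_threshold_boundary(self):
        D2 = 0.4
        # two parallel edges exactly D2 apart -> contact with eps = 0
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 5, 0], [1, 5 + D2 * 0 + 0, 0]], dtype=float
        )
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [1.0, 3, 0], [0, 3, 0], [0, 3, D2], [0, 0, D2], [1, 0, D2]],
            dtype=float,
        )
        st = make_rod_state(verts)
        cs = detect_coil_collisions(st, D2=D2)
        # edge 0 ((0,0,0)-(1,0,0)) vs edge 5 ((0,0,D2)-(1,0,D2)) at distance D2
        pairs = set(zip(cs.ee_i.tolist(), cs.ee_j.tolist()))
        assert (0, 5) in pairs
        k = list(zip(cs.ee_i, cs.ee_j)).index((0, 5))
        assert cs.ee_eps[k] == pytest.approx(0.0, abs=1e-12)

    def test_no_contact_beyond_diameter(self):
        D2 = 0.4
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 3, 0], [0, 3, 1.01 * D2], [0, 0, 1.01 * D2], [-1, 0, 1.01 * D2]],
            dtype=float,
        )
        st = make_rod_state(verts)
        cs = detect_coil_collisions(st, D2=D2)
        assert (0, 3) not in set(zip(cs.ee_i.tolist(), cs.ee_j.tolist()))

    def test_detection_matches_brute_force_random_tangles(self):
        D2 = 0.3
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            pts = np.cumsum(rng.normal(0, 0.2, (80, 3)), axis=0)
            st = make_rod_state(pts)
            cs = detect_coil_collisions(st, D2=D2)
            got = set(zip(cs.ee_i.tolist(), cs.ee_j.tolist()))
            # brute-force all-pairs evaluation of the same two-phase
            # rule: center condition first, then the exact distance
            expected = set()
            for (i, j) in brute_force_candidates(pts, D2):
                d, _, _ = min_distance_segments(pts[i], pts[i + 1], pts[j], pts[j + 1])
                if d <= D2:
                    expected.add((i, j))
            assert got == expected


def make_floor(size=10.0, z=0.0):
    v = np.array(
        [[-size, -size, z], [size, -size, z], [size, size, z], [-size, size, z]]
    )
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return WallSurface(v, f)


class TestWallDetection:
    def test_node_above_triangle_interior(self):
        D2 = 0.4
        wall = make_floor()
        pts = np.array([[0.3, 0.2, D2 / 4]])
        cs = detect_wall_collisions(pts, wall, D2)
        assert cs.n_wall == 1
        assert cs.nt_dist[0] == pytest.approx(D2 / 4)
        # penetration depth D2/2 - d = D2/4
        assert (D2 / 2 - cs.nt_dist[0]) == pytest.approx(D2 / 4)

    def test_literal_projection_mode_ignores_edge_proximity(self):
        D2 = 0.4
        v = np.array([[0, 0, 0.0], [1, 0, 0], [0, 1, 0]])
        f = np.array([[0, 1, 2]])
        wall = WallSurface(v, f)
        # point whose in-plane projection is outside the triangle but
        # whose closest feature (the edge) is within reach
        p = np.array([[-0.05, 0.5, 0.05]])
        literal = detect_wall_collisions(p, wall, D2, literal_projection=True)
        robust = detect_wall_collisions(p, wall, D2, literal_projection=False)
        assert literal.n_wall == 0
        assert robust.n_wall == 1

    def test_sphere_interior_distance_analytic(self, rng):
        import trimesh

        R = 2.0
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=R)
        wall = WallSurface.from_trimesh(mesh)
        D2 = 0.5
        for _ in range(10):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r0 = R - rng.uniform(0.01, D2 / 2)
            cs = detect_wall_collisions((r0 * u)[None, :], wall, D2)
            assert cs.n_wall == 1
            # distance to the mesh matches R - r0 up to faceting error
            assert cs.nt_dist[0] == pytest.approx(R - r0, abs=0.02)


class TestForces:
    def test_no_overlap_no_force(self):
        params = FrictionParams()
        F = coil_coil_normal_force(
            np.array([-0.01]), np.array([[0.3, 0, 0]]), np.zeros((1, 3)), params
        )
        assert np.allclose(F, 0.0)

    def test_static_overlap_magnitude(self):
        params = FrictionParams(k_sc=100.0, gamma_sc=0.0)
        eps = np.array([0.05])
        dvec = np.array([[0.25, 0, 0]])
        F = coil_coil_normal_force(eps, dvec, np.zeros((1, 3)), params)
        # |F| = k eps |d_min|, directed along -d_min (repulsive on edge 1)
        assert np.isclose(np.linalg.norm(F), 100.0 * 0.05 * 0.25)
        assert F[0, 0] < 0

    def test_dissipation_opposes_closing(self):
        params = FrictionParams(k_sc=0.0, gamma_sc=2.0)
        eps = np.array([0.01])
        dvec = np.array([[0.2, 0, 0]])  # edge 2 lies in +x from edge 1
        closing = np.array([[1.0, 0, 0]])  # edge 1 moving toward edge 2
        F = coil_coil_normal_force(eps, dvec, closing, params)
        assert F[0, 0] < 0  # pushes edge 1 back in -x

    def test_coil_friction_zero_without_tangential_velocity(self):
        params = FrictionParams()
        F = coil_coil_friction(
            np.array([[0.5, 0, 0]]), np.array([[0.2, 0, 0]]), np.array([1.0]), params
        )
        # relative velocity purely along the contact normal -> no slip force
        assert np.allclose(F, 0.0)

    def test_coil_friction_magnitude_and_direction(self, rng):
        params = FrictionParams(mu_slip_cc=0.4)
        for _ in range(50):
            dvec = rng.normal(size=(1, 3))
            rel = rng.normal(size=(1, 3))
            fn = rng.uniform(0.1, 2.0, 1)
            F = coil_coil_friction(rel, dvec, fn, params)
            v_par = rel - (rel @ dvec.T) / (dvec @ dvec.T) * dvec
            if np.linalg.norm(v_par) < 1e-12:
                continue
            assert np.isclose(np.linalg.norm(F), 0.4 * fn[0], rtol=1e-9)
            assert float(np.sum(F * v_par)) <= 0.0

    def test_wall_reaction_cancels_pressing_force(self):
        params = FrictionParams(k_w=50.0, gamma_w=0.0)
        n = np.array([[0.0, 0, 1.0]])
        eps = np.array([0.02])
        f_elastic = np.array([[0.0, 0, 3.0]])  # pressing along +n
        F, f_perp = wall_normal_force(eps, n, f_elastic, np.zeros((1, 3)), params)
        assert f_perp[0] == pytest.approx(3.0)
        assert np.allclose(F, [[0, 0, -(3.0 + 50.0 * 0.02)]])

    def test_wall_reaction_tangential_only_elastic(self):
        params = FrictionParams(k_w=50.0, gamma_w=0.0)
        n = np.array([[0.0, 0, 1.0]])
        eps = np.array([0.02])
        f_elastic = np.array([[2.0, 0, 0.0]])
        F, f_perp = wall_normal_force(eps, n, f_elastic, np.zeros((1, 3)), params)
        assert f_perp[0] == 0.0
        assert np.allclose(F, [[0, 0, -1.0]])

    def test_wall_stick_cancels_small_tangential_force(self):
        params = FrictionParams(mu_stick_cw=0.6, mu_slip_cw=0.4, v_eps=1e-3)
        n = np.array([[0.0, 0, 1.0]])
        f = np.array([[0.1, 0, 5.0]])
        Ff = wall_friction(n, f, np.zeros((1, 3)), np.array([5.0]), params)
        assert np.allclose(Ff, [[-0.1, 0, 0]], atol=1e-12)

    def test_wall_stick_caps_large_tangential_force(self):
        params = FrictionParams(mu_stick_cw=0.6, mu_slip_cw=0.4, v_eps=1e-3)
        n = np.array([[0.0, 0, 1.0]])
        f = np.array([[10.0, 0, 5.0]])
        Ff = wall_friction(n, f, np.zeros((1, 3)), np.array([5.0]), params)
        assert np.isclose(np.linalg.norm(Ff), 0.6 * 5.0)
        assert Ff[0, 0] < 0

    def test_wall_slip_opposes_motion(self):
        params = FrictionParams(mu_stick_cw=0.6, mu_slip_cw=0.4, v_eps=1e-3)
        n = np.array([[0.0, 0, 1.0]])
        v = np.array([[2.0, 0, 0.5]])
        Ff = wall_friction(n, np.zeros((1, 3)), v, np.array([3.0]), params)
        assert np.isclose(np.linalg.norm(Ff), 0.4 * 3.0)
        assert Ff[0, 0] < 0 and Ff[0, 2] == 0.0

    def test_wall_stick_zero_tangential_force(self):
        params = FrictionParams()
        n = np.array([[0.0, 0, 1.0]])
        Ff = wall_friction(n, np.array([[0.0, 0, 1.0]]), np.zeros((1, 3)), np.array([1.0]), params)
        assert np.allclose(Ff, 0.0)


class TestAssembly:
    def test_far_from_everything_zero(self, rng):
        from aneucoil.contact import assemble_external_forces

        st = random_rod(rng, 20)
        st.vertices += 100.0
        wall = make_floor(z=-50.0)
        F, diag = assemble_external_forces(
            st, [wall], FrictionParams(), 0.3, np.zeros((20, 3))
        )
        assert np.allclose(F, 0.0)
        assert diag.n_coil_pairs == 0 and diag.n_wall == 0

    def test_pair_forces_antisymmetric(self, rng):
        from aneucoil.contact import assemble_external_forces

        # a tangled rod with only self contact: total momentum input zero
        pts = np.cumsum(rng.normal(0, 0.2, (60, 3)), axis=0)
        st = make_rod_state(pts)
        st.velocities = rng.normal(0, 1.0, (60, 3))
        wall = make_floor(z=-1e3)
        F, diag = assemble_external_forces(
            st, [wall], FrictionParams(), 0.35, np.zeros((60, 3))
        )
        assert diag.antisymmetry_residual < 1e-10
        assert np.linalg.norm(F.sum(axis=0)) < 1e-10

    def test_forces_bounded_without_deep_interpenetration(self, rng):
        from aneucoil.contact import assemble_external_forces

        params = FrictionParams(k_sc=100.0, gamma_sc=0.0, k_w=50.0, gamma_w=0.0)
        pts = np.cumsum(rng.normal(0, 0.2, (50, 3)), axis=0)
        st = make_rod_state(pts)
        D2 = 0.35
        F, diag = assemble_external_forces(st, [make_floor(z=-1e3)], params, D2, np.zeros((50, 3)))
        # per-contact force bounded by k * D2 * |d| <= k * D2^2; each
        # edge can touch at most O(n) partners
        assert np.abs(F).max() <= params.k_sc * D2 * D2 * 50
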