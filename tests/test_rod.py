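"""Discrete rod kernel: frames, curvature, twist, energy, gradients."""

import numpy as np
import pytest

from conftest import random_natural, random_rod

from aneucoil.rod import (
    CoilSpec,
    DegenerateTurnError,
    NaturalShape,
    curvature_binormal,
    discrete_curvatures,
    grad_energy,
    make_rod_state,
    material_directors,
    measure_twist,
    propagate_bishop,
    rodrigues_rotation,
    stiffness_from_microstructure,
    total_energy,
)


def fd_gradient(state, natural, spec, h=1e-7):
    """Central finite differences of the energy, the gradient oracle.

    Frames are recomputed from the same first-edge reference director,
    so the perturbed energies live on the same parametrization."""
    u_ref = state.bishop_U[0].copy()
    phi = state.edge_angles

    def energy(X, p):
        return total_energy(
            make_rod_state(X, edge_angles=p, reference_director=u_ref), natural, spec
        )

    X = state.vertices
    gX = np.zeros_like(X)
    for i in range(len(X)):
        for k in range(3):
            Xp = X.copy(); Xp[i, k] += h
            Xm = X.copy(); Xm[i, k] -= h
            gX[i, k] = (energy(Xp, phi) - energy(Xm, phi)) / (2 * h)
    gP = np.zeros_like(phi)
    for j in range(len(phi)):
        pp = phi.copy(); pp[j] += h
        pm = phi.copy(); pm[j] -= h
        gP[j] = (energy(X, pp) - energy(X, pm)) / (2 * h)
    return gX, gP


class TestCurvatureBinormal:
    def test_collinear_tangents_vanish(self):
        t = np.array([0.6, 0.8, 0.0])
        assert np.allclose(curvature_binormal(t, t), 0.0)

    def test_right_angle(self):
        kb = curvature_binormal(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        assert np.allclose(kb, [0, 0, 2.0])

    @pytest.mark.parametrize("n", [8, 32, 128])
    def test_polygon_curvature_approaches_circle(self, n):
        # nodal curvature over Voronoi length tends to 1/R for an
        # inscribed regular polygon; error shrinks ~ n^-2
        R = 2.0
        ang = 2 * np.pi * np.arange(n + 2) / n
        pts = R * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n + 2)])
        st = make_rod_state(pts)
        t = st.tangents
        kb = curvature_binormal(t[0], t[1])
        lbar = 0.5 * (st.edge_lengths[0] + st.edge_lengths[1])
        err = abs(np.linalg.norm(kb) / lbar - 1.0 / R) * R
        assert err < 20.0 / n**2

    def test_antiparallel_raises(self):
        with pytest.raises(DegenerateTurnError):
            curvature_binormal(np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]))


class TestDiscreteCurvatures:
    def test_straight_rod_zero(self, rng):
        pts = np.outer(np.arange(7), [1.0, 0.3, -0.2])
        st = make_rod_state(pts, edge_angles=rng.normal(0, 1, 6))
        assert np.allclose(discrete_curvatures(st), 0.0, atol=1e-12)

    def test_planar_arc_components(self):
        # arc in the xy-plane; with the material frame's second director
        # along +z (the arc binormal), kappa_2 = 0 and kappa_1 = |kb|
        R, n = 1.5, 12
        ang = np.linspace(0, 1.0, n)
        pts = R * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
        st = make_rod_state(pts, reference_director=np.array([0, 0, 1.0]))
        d1, d2 = material_directors(st)
        # rotate phi so that D2 == +z on every edge
        phi = np.arctan2(
            np.einsum("ij,j->i", st.bishop_U, np.array([0, 0, 1.0])),
            np.einsum("ij,j->i", st.bishop_V, np.array([0, 0, 1.0])),
        )
        st.edge_angles = -phi + np.pi / 2 * 0  # D2 = -sin(phi)U + cos(phi)V
        st.edge_angles = phi
        d1, d2 = material_directors(st)
        # ensure construction succeeded before asserting the physics
        assert np.allclose(np.abs(d2[:, 2]), 1.0, atol=1e-9)
        kappa = discrete_curvatures(st)
        t = st.tangents
        kb = curvature_binormal(t[:-1], t[1:])
        sign = np.sign(d2[0, 2])
        assert np.allclose(kappa[:, 1], 0.0, atol=1e-9)
        assert np.allclose(kappa[:, 0] * sign, np.linalg.norm(kb, axis=1), atol=1e-9)

    @pytest.mark.parametrize("theta", np.linspace(0.2, 6.0, 7))
    def test_frame_rotation_rotates_components(self, rng, theta):
        st = random_rod(rng, 9)
        k0 = discrete_curvatures(st)
        st2 = st.copy()
        st2.edge_angles = st.edge_angles + theta
        k1 = discrete_curvatures(st2)
        rot = np.array(
            [[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]]
        )
        assert np.allclose(k1, k0 @ rot.T, atol=1e-9)
        assert np.allclose(
            np.linalg.norm(k1, axis=1), np.linalg.norm(k0, axis=1), atol=1e-12
        )


class TestRodrigues:
    def test_identity(self):
        t = np.array([0, 0.6, 0.8])
        assert np.allclose(rodrigues_rotation(t, t), np.eye(3))

    def test_quarter_turn_matches_axis_angle(self):
        R = rodrigues_rotation(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        c, s = np.cos(np.pi / 2), np.sin(np.pi / 2)
        expected = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        assert np.allclose(R, expected, atol=1e-12)

    def test_rotation_properties_random(self, rng):
        for _ in range(100):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            a /= np.linalg.norm(a)
            b /= np.linalg.norm(b)
            if np.dot(a, b) < -0.99:
                continue
            R = rodrigues_rotation(a, b)
            assert np.allclose(R @ a, b, atol=1e-10)
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)
            assert np.isclose(np.linalg.det(R), 1.0, atol=1e-10)
            v = rng.normal(size=3)
            assert np.isclose(np.linalg.norm(R @ v), np.linalg.norm(v), atol=1e-10)


class TestBishopFrame:
    def test_straight_rod_constant_triads(self):
        pts = np.outer(np.arange(6), [1.0, 0, 0])
        st = make_rod_state(pts)
        assert np.allclose(st.bishop_U, st.bishop_U[0])
        assert np.allclose(st.bishop_V, st.bishop_V[0])

    def test_helix_frame_is_twist_free(self):
        s = np.linspace(0, 30, 200)
        r, c = 1.0, 0.2
        w = np.sqrt(r**2 + c**2)
        pts = np.column_stack([r * np.cos(s / w), r * np.sin(s / w), c * s / w])
        st = make_rod_state(pts)
        assert np.abs(measure_twist(st)).max() < 1e-10

    def test_orthonormality_preserved(self, rng):
        st = random_rod(rng, 200)
        st = propagate_bishop(st)
        t = st.tangents
        for A, B in ((st.bishop_U, st.bishop_V), (st.bishop_V, t), (st.bishop_U, t)):
            assert np.abs(np.sum(A * B, axis=1)).max() < 1e-10
        assert np.abs(np.linalg.norm(st.bishop_U, axis=1) - 1).max() < 1e-10
        assert np.allclose(np.cross(t, st.bishop_U), st.bishop_V, atol=1e-10)

    def test_planar_loop_zero_holonomy(self):
        # a closed square path: parallel transport around it returns the
        # initial frame (planar curves carry no holonomy)
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]],
            dtype=float,
        )
        st = make_rod_state(pts, reference_director=np.array([0, 0.3, 1.0]))
        # first and last edge have identical tangents; compare triads
        assert np.allclose(st.bishop_U[0], st.bishop_U[-1], atol=1e-12)
        assert np.allclose(st.bishop_V[0], st.bishop_V[-1], atol=1e-12)


class TestMeasureTwist:
    def test_uniform_angles_zero(self, rng):
        st = random_rod(rng, 10, angles=False)
        st.edge_angles[:] = 0.7
        assert np.allclose(measure_twist(st), 0.0)

    def test_simple_increment(self):
        pts = np.outer(np.arange(3), [1.0, 0, 0])
        st = make_rod_state(pts, edge_angles=np.array([0.0, np.pi / 4]))
        assert np.isclose(measure_twist(st, 1), np.pi / 4)

    def test_axis_pointing_frame_has_constant_twist(self):
        # a material frame whose first director points at the helix axis
        # twists by a constant increment per edge equal to the helix
        # torsion integrated over one edge: tau = c/(r^2+c^2) * ds
        r, spacing, n_per_turn, turns = 1.0, 0.3, 40, 4
        c = spacing / (2 * np.pi)
        w = np.sqrt(r**2 + c**2)
        s = np.linspace(0, 2 * np.pi * w * turns, n_per_turn * turns + 1)
        pts = np.column_stack([r * np.cos(s / w), r * np.sin(s / w), c * s / w])
        st = make_rod_state(pts)
        # choose phi per edge so that D1 points toward the axis
        mid = 0.5 * (pts[:-1] + pts[1:])
        to_axis = -np.column_stack([mid[:, 0], mid[:, 1], np.zeros(len(mid))])
        phi = np.arctan2(
            np.einsum("ij,ij->i", st.bishop_V, to_axis),
            np.einsum("ij,ij->i", st.bishop_U, to_axis),
        )
        st.edge_angles = phi
        tau = measure_twist(st)
        ds = 2 * np.pi * w / n_per_turn
        expected = c / w**2 * ds
        assert np.allclose(tau, expected, rtol=0.02)
        assert tau.std() / tau.mean() < 1e-6  # constant increment

    def test_alignment_identity(self, rng):
        # D1^j equals the parallel-transported previous frame rotated by tau
        st = random_rod(rng, 12)
        d1, d2 = material_directors(st)
        t = st.tangents
        tau = measure_twist(st)
        for j in range(1, st.n_vertices - 1):
            R = rodrigues_rotation(t[j - 1], t[j])
            pred = np.cos(tau[j - 1]) * (R @ d1[j - 1]) + np.sin(tau[j - 1]) * (R @ d2[j - 1])
            assert np.allclose(d1[j], pred, atol=1e-9)


class TestEnergy:
    def test_zero_at_natural_shape(self, rng, coil_spec):
        nat = random_natural(rng, 10)
        st = make_rod_state(nat.natural_vertices)
        assert total_energy(st, nat, coil_spec) < 1e-18
        gX, gP = grad_energy(st, nat, coil_spec)
        assert np.abs(gX).max() < 1e-12
        assert np.abs(gP).max() < 1e-12

    def test_pure_twist_energy(self, coil_spec):
        # straight rod, straight natural shape, phi = (0, theta):
        # E = beta theta^2 / (2 lbar)
        theta = 0.3
        pts = np.outer(np.arange(3), [0.4, 0, 0])
        nat = NaturalShape.from_vertices(pts)
        st = make_rod_state(pts, edge_angles=np.array([0.0, theta]))
        beta = coil_spec.twist_stiffness
        expected = beta * theta**2 / (2 * 0.4)
        assert np.isclose(total_energy(st, nat, coil_spec), expected, rtol=1e-12)

    def test_uniform_stretch_energy(self, coil_spec):
        s = 0.02
        pts = np.outer(np.arange(5), [0.5, 0, 0])
        nat = NaturalShape.from_vertices(pts)
        st = make_rod_state(pts * (1 + s))
        expected = sum(
            0.5 * coil_spec.axial_penalty * s**2 * l for l in nat.rest_edge_lengths
        )
        assert np.isclose(total_energy(st, nat, coil_spec), expected, rtol=1e-10)

    def test_rigid_motion_invariance(self, rng, coil_spec):
        nat = random_natural(rng, 12)
        st = random_rod(rng, 12)
        e0 = total_energy(st, nat, coil_spec)
        # random rotation + translation; rotate the frame seed as well
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        Rm = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        shift = rng.normal(size=3) * 5
        st2 = make_rod_state(
            st.vertices @ Rm.T + shift,
            edge_angles=st.edge_angles,
            reference_director=Rm @ st.bishop_U[0],
        )
        e1 = total_energy(st2, nat, coil_spec)
        assert np.isclose(e0, e1, rtol=1e-8)

    def test_nonnegative_random(self, rng, coil_spec):
        for _ in range(20):
            nat = random_natural(rng, 8)
            st = random_rod(rng, 8)
            assert total_energy(st, nat, coil_spec) >= 0.0


class TestGradient:
    @pytest.mark.parametrize("trial", range(6))
    def test_matches_finite_differences(self, trial, coil_spec):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 13))
        st = random_rod(rng, n)
        nat = random_natural(rng, n)
        gX, gP = grad_energy(st, nat, coil_spec)
        fX, fP = fd_gradient(st, nat, coil_spec)
        scale = max(np.abs(fX).max(), 1e-9)
        assert np.abs(gX - fX).max() / scale < 1e-5
        scale_p = max(np.abs(fP).max(), 1e-9)
        assert np.abs(gP - fP).max() / scale_p < 1e-5

    def test_twist_only_phi_gradient(self, coil_spec):
        # straight rod: grad_Phi is the telescoped beta * tau / lbar pattern
        pts = np.outer(np.arange(5), [0.4, 0, 0])
        nat = NaturalShape.from_vertices(pts)
        phi = np.array([0.0, 0.2, 0.5, 0.1])
        st = make_rod_state(pts, edge_angles=phi)
        _, gP = grad_energy(st, nat, coil_spec)
        beta = coil_spec.twist_stiffness
        tau = np.diff(phi)
        lbar = nat.voronoi_lengths
        expected = np.zeros(4)
        expected[1:] += beta * tau / lbar
        expected[:-1] -= beta * tau / lbar
        assert np.allclose(gP, expected, rtol=1e-10)


class TestStiffness:
    def test_hand_computed_values(self):
        # single-formula hand evaluation, frozen:
        # b = E D1^4 p_c / (32 (2+mu) D2), beta = E D1^4 p_c / (64 D2)
        b, beta = stiffness_from_microstructure(0.05, 0.305, 168e9, 0.38, 1.1)
        assert np.isclose(b, 2.4861378977820645, rtol=1e-12)
        assert np.isclose(beta, 2.958504098360657, rtol=1e-12)

    def test_ratio(self):
        b, beta = stiffness_from_microstructure(0.04, 0.4, 100e9, 0.25, 1.3)
        assert np.isclose(beta / b, (2 + 0.25) / 2, rtol=1e-12)

    def test_zero_poisson_ratio_limit(self):
        b, beta = stiffness_from_microstructure(0.05, 0.305, 168e9, 0.0, 1.1)
        assert np.isclose(beta / b, 1.0, rtol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stiffness_from_microstructure(-0.05, 0.305, 168e9, 0.38, 1.1)
        with pytest.raises(ValueError):
            stiffness_from_microstructure(0.05, 0.305, 168e9, 0.38, 0.9)

    def test_coil_spec_invariants(self, coil_spec):
        assert coil_spec.bend_stiffness > 0
        assert coil_spec.twist_stiffness / coil_spec.bend_stiffness == pytest.approx(
            (2 + coil_spec.mu_w) / 2
        )
        with pytest.raises(ValueError):
            CoilSpec(D1=0.4, D2=0.3, D3=2.0)
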