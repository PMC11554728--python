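"""Geometry and elasticity of a discrete elastic rod.

A medical embolization coil is modelled as a Kirchhoff rod discretized on a
polyline: ``N`` material points connected by ``N-1`` edges.  Each edge
carries an adapted orthonormal frame whose third director is the unit
tangent.  The twist degree of freedom is parametrized by a scalar angle
``phi`` per edge measured against the twist-free Bishop frame, which is
obtained by parallel transport along the centerline.  The strain energy has
three parts:

* an axial penalty ``alpha/2 * (|e|/|e_bar| - 1)^2 * |e_bar|`` per edge that
  enforces inextensibility approximately,
* a bending part ``(kappa - kappa_bar) B (kappa - kappa_bar) / (2 l_bar)``
  at interior nodes, with ``B = b I`` and the imprinted natural curvature
  ``kappa_bar``,
* a twisting part ``beta (tau - tau_bar)^2 / (2 l_bar)`` per interior edge,
  with natural twist ``tau_bar = 0`` (the natural shape is Bishop-framed).

Internal unit system: millimetre, second, kilogram.  The derived force unit
is then 1 kg mm / s^2 = 1 mN and energies are in mN mm (micro-joule).
Young's moduli are accepted in Pa at the API boundary and converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RodState",
    "NaturalShape",
    "CoilSpec",
    "DegenerateTurnError",
    "curvature_binormal",
    "discrete_curvatures",
    "rodrigues_rotation",
    "propagate_bishop",
    "measure_twist",
    "total_energy",
    "grad_energy",
    "stiffness_from_microstructure",
    "material_directors",
    "make_rod_state",
    "PA_TO_MN_PER_MM2",
    "PLATINUM_DENSITY_KG_MM3",
    "AXIAL_REFERENCE_STIFFNESS_MN",
]

#: conversion factor Pa -> mN/mm^2 (1 Pa = 1e-3 mN/mm^2)
PA_TO_MN_PER_MM2 = 1.0e-3

#: platinum density in kg/mm^3 (21450 kg/m^3)
PLATINUM_DENSITY_KG_MM3 = 21450.0e-9

#: Reference axial stiffness scale (mN).  The dimensionless penalty
#: parameter ``alpha`` multiplies this constant to give the absolute axial
#: stiffness (force per unit strain) used in the energy.  The scale was
#: calibrated once on the synthetic-dome deployment scenario so that
#: ``alpha = 0.1`` keeps the mean relative segment stretch below 1% while
#: the smallest tabulated value ``alpha = 0.025`` sits near the 1.5%
#: regime, and is frozen.
AXIAL_REFERENCE_STIFFNESS_MN = 1.5e3

_EPS_ANTIPARALLEL = 1.0e-10


class DegenerateTurnError(ValueError):
    """Raised when two consecutive tangents are (numerically) antiparallel.

    A 180-degree kink makes the discrete curvature and the parallel
    transport rotation singular and lies outside the model's validity.
    """


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RodState:
    """Discrete state of one rod (or several virtually connected rods).

    Attributes
    ----------
    vertices : (N, 3) float array, mm
    edge_angles : (N-1,) float array, rad
        Material-frame rotation ``phi`` about the tangent, measured against
        the Bishop frame of the current centerline.
    velocities : (N, 3) float array, mm/s
    bishop_U, bishop_V : (N-1, 3) float arrays
        First two legs of the per-edge Bishop triad ``{U, V, t}``.
    release_step : (N,) int array
        Time-step index at which each vertex left the micro-catheter,
        -1 while still inside.
    """

    vertices: np.ndarray
    edge_angles: np.ndarray
    velocities: np.ndarray
    bishop_U: np.ndarray
    bishop_V: np.ndarray
    release_step: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> np.ndarray:
        return self.vertices[1:] - self.vertices[:-1]

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edges, axis=1)

    @property
    def tangents(self) -> np.ndarray:
        e = self.edges
        ln = np.linalg.norm(e, axis=1)
        if np.any(ln <= 0.0):
            raise ValueError("rod has a zero-length edge")
        return e / ln[:, None]

    def copy(self) -> "RodState":
        return RodState(
            self.vertices.copy(),
            self.edge_angles.copy(),
            self.velocities.copy(),
            self.bishop_U.copy(),
            self.bishop_V.copy(),
            self.release_step.copy(),
        )


@dataclass
class NaturalShape:
    """Stress-free (imprinted) configuration of a coil.

    ``natural_curvatures`` are the integrated discrete curvatures of the
    natural centerline measured in its own Bishop frame; the natural twist
    is identically zero in this parametrization.
    """

    natural_vertices: np.ndarray
    rest_edge_lengths: np.ndarray
    voronoi_lengths: np.ndarray
    natural_curvatures: np.ndarray
    natural_twist: np.ndarray

    @classmethod
    def from_vertices(cls, vertices: np.ndarray) -> "NaturalShape":
        vertices = np.asarray(vertices, dtype=float)
        edges = vertices[1:] - vertices[:-1]
        lengths = np.linalg.norm(edges, axis=1)
        if np.any(lengths <= 0.0):
            raise ValueError("natural shape has a zero-length edge")
        voronoi = 0.5 * (lengths[:-1] + lengths[1:])
        state = make_rod_state(vertices)
        kappa = discrete_curvatures(state)
        tau = np.zeros(max(len(lengths) - 1, 0))
        return cls(vertices, lengths, voronoi, kappa, tau)

    @property
    def total_length(self) -> float:
        return float(self.rest_edge_lengths.sum())


@dataclass
class CoilSpec:
    """Physical description of one coil and its derived rod constants.

    Parameters
    ----------
    D1, D2, D3 : float, mm
        Stock-wire diameter, coil (rod) diameter and imprint diameter.
    E_w : float, Pa
        Young's modulus of the stock wire.
    mu_w : float
        Poisson ratio of the stock wire.
    pitch : float
        Dimensionless winding pitch ``p > 1`` of the stock wire;
        the turn spacing is ``p_c = D1 * p``.
    length : float, mm
        Nominal arc length of the coil.
    alpha : float
        Dimensionless axial penalty parameter; the absolute stiffness is
        ``alpha * AXIAL_REFERENCE_STIFFNESS_MN``.
    """

    D1: float
    D2: float
    D3: float
    E_w: float = 168.0e9
    mu_w: float = 0.38
    pitch: float = 1.1
    length: float = 100.0
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.D1 < self.D2 < self.D3):
            raise ValueError("coil diameters must satisfy 0 < D1 < D2 < D3")
        if self.pitch <= 1.0:
            raise ValueError("pitch must be > 1")

    @property
    def p_c(self) -> float:
        return self.D1 * self.pitch

    @property
    def bend_stiffness(self) -> float:
        """Bending stiffness ``b`` in mN mm^2 (isotropic, B = b I)."""
        b, _ = stiffness_from_microstructure(
            self.D1, self.D2, self.E_w, self.mu_w, self.pitch
        )
        return b

    @property
    def twist_stiffness(self) -> float:
        """Twisting stiffness ``beta`` in mN mm^2."""
        _, beta = stiffness_from_microstructure(
            self.D1, self.D2, self.E_w, self.mu_w, self.pitch
        )
        return beta

    @property
    def axial_penalty(self) -> float:
        """Absolute axial stiffness ``alpha_abs`` in mN (force per strain)."""
        return self.alpha * AXIAL_REFERENCE_STIFFNESS_MN

    def wire_length_per_mm(self) -> float:
        """Arc length of stock wire wound into 1 mm of coil."""
        return np.pi * self.D2 / self.p_c

    def node_mass(self, l_rest: float) -> float:
        """Lumped node mass (kg) for a segment of rest length ``l_rest``.

        Platinum density times the stock-wire volume contained in one
        segment of the wound coil.
        """
        wire_volume = np.pi * (self.D1 / 2.0) ** 2 * self.wire_length_per_mm() * l_rest
        return PLATINUM_DENSITY_KG_MM3 * wire_volume


# ---------------------------------------------------------------------------
# kernel operations
# ---------------------------------------------------------------------------


def stiffness_from_microstructure(
    D1: float, D2: float, E_w: float, mu_w: float, p: float
) -> tuple[float, float]:
    """Bending and twisting stiffness of a wound (torsion-spring like) coil.

    The rod of diameter ``D2`` is a tight helix of stock wire of diameter
    ``D1``; its effective stiffnesses are

    ``b = E_w D1^4 p_c / (32 (2 + mu_w) D2)``,
    ``beta = E_w D1^4 p_c / (64 D2)``,  ``p_c = D1 p``.

    Parameters are in mm / Pa; the result is in mN mm^2.
    """
    if min(D1, D2, E_w, p) <= 0.0 or mu_w < 0.0:
        raise ValueError("stiffness inputs must be positive (mu_w >= 0)")
    if p <= 1.0:
        raise ValueError("pitch must be > 1")
    E = E_w * PA_TO_MN_PER_MM2
    p_c = D1 * p
    b = E * D1**4 * p_c / (32.0 * (2.0 + mu_w) * D2)
    beta = E * D1**4 * p_c / (64.0 * D2)
    return b, beta


def curvature_binormal(t_prev: np.ndarray, t_next: np.ndarray) -> np.ndarray:
    """Nodal discrete integrated curvature binormal.

    ``(kappa b) = 2 (t_prev x t_next) / (1 + t_prev . t_next)``.

    Accepts single vectors or stacked arrays of shape (M, 3).
    """
    t_prev = np.asarray(t_prev, dtype=float)
    t_next = np.asarray(t_next, dtype=float)
    dot = np.sum(t_prev * t_next, axis=-1)
    if np.any(dot <= -1.0 + _EPS_ANTIPARALLEL):
        raise DegenerateTurnError("antiparallel consecutive tangents (180 degree kink)")
    return 2.0 * np.cross(t_prev, t_next) / (1.0 + dot)[..., None]


def material_directors(state: RodState) -> tuple[np.ndarray, np.ndarray]:
    """Material directors ``D1 = cos(phi) U + sin(phi) V`` and
    ``D2 = -sin(phi) U + cos(phi) V`` per edge."""
    c = np.cos(state.edge_angles)[:, None]
    s = np.sin(state.edge_angles)[:, None]
    d1 = c * state.bishop_U + s * state.bishop_V
    d2 = -s * state.bishop_U + c * state.bishop_V
    return d1, d2


def discrete_curvatures(state: RodState, node_index: int | None = None) -> np.ndarray:
    """Discrete material curvatures ``(kappa_1, kappa_2)`` at interior nodes.

    ``kappa_i1 = 1/2 (D2^{i-1} + D2^i) . (kb)_i``,
    ``kappa_i2 = -1/2 (D1^{i-1} + D1^i) . (kb)_i``.

    Returns an ``(N-2, 2)`` array for nodes ``1..N-2``; if ``node_index``
    is given, the single 2-vector for that node.
    """
    t = state.tangents
    kb = curvature_binormal(t[:-1], t[1:])
    d1, d2 = material_directors(state)
    k1 = 0.5 * np.sum((d2[:-1] + d2[1:]) * kb, axis=1)
    k2 = -0.5 * np.sum((d1[:-1] + d1[1:]) * kb, axis=1)
    kappa = np.column_stack([k1, k2])
    if node_index is not None:
        if not (1 <= node_index <= state.n_vertices - 2):
            raise IndexError("curvature is defined at interior nodes only")
        return kappa[node_index - 1]
    return kappa


def rodrigues_rotation(t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector ``t_from`` onto ``t_to``.

    ``R = I + K + K^2 / (1 + t_from . t_to)`` with ``K v = (t_from x t_to) x v``.
    This is the minimal (geodesic) rotation used for parallel transport.
    """
    t_from = np.asarray(t_from, dtype=float)
    t_to = np.asarray(t_to, dtype=float)
    dot = float(np.dot(t_from, t_to))
    if dot <= -1.0 + _EPS_ANTIPARALLEL:
        raise DegenerateTurnError("cannot parallel transport across a 180 degree turn")
    axis = np.cross(t_from, t_to)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + K + (K @ K) / (1.0 + dot)


def _transport_kernel(t: np.ndarray, U: np.ndarray, V: np.ndarray) -> None:
    """Parallel-transport loop: ``U[0]``/``V[0]`` preset, fills the rest.

    ``R u = u + a x u + a x (a x u) / (1 + d)`` with ``a = t_prev x t_next``
    followed by re-orthogonalization against the tangent to stop drift.
    """
    for j in range(1, len(t)):
        px, py, pz = t[j - 1, 0], t[j - 1, 1], t[j - 1, 2]
        qx, qy, qz = t[j, 0], t[j, 1], t[j, 2]
        d = px * qx + py * qy + pz * qz
        ax = py * qz - pz * qy
        ay = pz * qx - px * qz
        az = px * qy - py * qx
        ux, uy, uz = U[j - 1, 0], U[j - 1, 1], U[j - 1, 2]
        c1x = ay * uz - az * uy
        c1y = az * ux - ax * uz
        c1z = ax * uy - ay * ux
        inv = 1.0 / (1.0 + d)
        c2x = (ay * c1z - az * c1y) * inv
        c2y = (az * c1x - ax * c1z) * inv
        c2z = (ax * c1y - ay * c1x) * inv
        ux = ux + c1x + c2x
        uy = uy + c1y + c2y
        uz = uz + c1z + c2z
        proj = ux * qx + uy * qy + uz * qz
        ux -= proj * qx
        uy -= proj * qy
        uz -= proj * qz
        norm = (ux * ux + uy * uy + uz * uz) ** 0.5
        ux /= norm
        uy /= norm
        uz /= norm
        U[j, 0], U[j, 1], U[j, 2] = ux, uy, uz
        V[j, 0] = qy * uz - qz * uy
        V[j, 1] = qz * ux - qx * uz
        V[j, 2] = qx * uy - qy * ux


try:  # jit the transport loop; fall back to pure Python if unavailable
    from numba import njit as _njit

    _transport_kernel = _njit(cache=True)(_transport_kernel)
except ImportError:  # pragma: no cover
    pass


def _transport_chain(tangents: np.ndarray, U0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel transport the triad seeded by ``U0`` along all edges."""
    n_edges = len(tangents)
    U = np.empty((n_edges, 3))
    V = np.empty((n_edges, 3))
    u = U0 - np.dot(U0, tangents[0]) * tangents[0]
    nu = np.linalg.norm(u)
    if nu < 1.0e-12:
        raise ValueError("reference director is parallel to the first tangent")
    u /= nu
    U[0] = u
    V[0] = np.cross(tangents[0], u)
    dots = np.sum(tangents[:-1] * tangents[1:], axis=1)
    if np.any(dots <= -1.0 + _EPS_ANTIPARALLEL):
        raise DegenerateTurnError("antiparallel consecutive tangents (180 degree kink)")
    _transport_kernel(np.ascontiguousarray(tangents), U, V)
    return U, V


def propagate_bishop(state: RodState, U0: np.ndarray | None = None) -> RodState:
    """Recompute the Bishop frame by parallel transport from the first edge.

    ``U^j = R(t^{j-1} -> t^j) U^{j-1}`` and likewise ``V``; the resulting
    frame is twist-free by construction.  ``U0`` seeds the first edge
    (default: the state's current first-edge director, re-adapted by
    projection, which introduces no first-order twist).
    """
    t = state.tangents
    seed = state.bishop_U[0] if U0 is None else np.asarray(U0, dtype=float)
    U, V = _transport_chain(t, seed)
    out = state.copy()
    out.bishop_U = U
    out.bishop_V = V
    return out


def make_rod_state(
    vertices: np.ndarray,
    edge_angles: np.ndarray | None = None,
    velocities: np.ndarray | None = None,
    reference_director: np.ndarray | None = None,
) -> RodState:
    """Build a :class:`RodState` with a freshly propagated Bishop frame."""
    vertices = np.asarray(vertices, dtype=float)
    n = len(vertices)
    if n < 2:
        raise ValueError("a rod needs at least two vertices")
    edges = vertices[1:] - vertices[:-1]
    lengths = np.linalg.norm(edges, axis=1)
    if np.any(lengths <= 0.0):
        raise ValueError("rod has a zero-length edge")
    t = edges / lengths[:, None]
    if reference_director is None:
        # any vector not parallel to the first tangent
        trial = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(trial, t[0])) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        reference_director = trial
    U, V = _transport_chain(t, np.asarray(reference_director, dtype=float))
    phi = np.zeros(n - 1) if edge_angles is None else np.asarray(edge_angles, dtype=float).copy()
    vel = np.zeros((n, 3)) if velocities is None else np.asarray(velocities, dtype=float).copy()
    return RodState(
        vertices.copy(),
        phi,
        vel,
        U,
        V,
        np.full(n, -1, dtype=np.int64),
    )


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    return np.where(np.isclose(w, -np.pi), np.pi, w)


def measure_twist(state: RodState, edge_index: int | None = None) -> np.ndarray:
    """Discrete integrated twist ``tau^j = phi^j - phi^{j-1}`` (wrapped).

    Because ``phi`` is measured against the twist-free Bishop frame, the
    increment of ``phi`` between consecutive edges is exactly the angle
    needed to align the parallel-transported material frame of edge
    ``j-1`` with that of edge ``j``.
    """
    tau = _wrap_angle(np.diff(state.edge_angles))
    if edge_index is not None:
        if edge_index < 1:
            raise IndexError("twist is defined for edges j >= 1")
        return tau[edge_index - 1]
    return tau


def _check_sizes(state: RodState, natural: NaturalShape) -> None:
    if len(natural.rest_edge_lengths) != state.n_vertices - 1:
        raise ValueError("natural shape and state have inconsistent sizes")


def total_energy(
    state: RodState,
    natural: NaturalShape,
    spec: CoilSpec,
    active_edges: np.ndarray | None = None,
) -> float:
    """Total discrete strain energy (mN mm): axial + bending + twist.

    ``active_edges`` is an optional boolean mask over edges; inactive
    (virtual inter-coil) edges are excluded from the axial and twist sums
    and both incident interior nodes are excluded from the bending sum.
    """
    _check_sizes(state, natural)
    b = spec.bend_stiffness
    beta = spec.twist_stiffness
    alpha_abs = spec.axial_penalty

    lengths = state.edge_lengths
    lbar_e = natural.rest_edge_lengths
    strain = lengths / lbar_e - 1.0
    axial_terms = 0.5 * alpha_abs * strain**2 * lbar_e

    kappa = discrete_curvatures(state)
    dk = kappa - natural.natural_curvatures
    lbar_v = natural.voronoi_lengths
    bend_terms = 0.5 * b * np.sum(dk * dk, axis=1) / lbar_v

    tau = measure_twist(state)
    dtau = tau - natural.natural_twist
    twist_terms = 0.5 * beta * dtau**2 / lbar_v

    if active_edges is not None:
        active_edges = np.asarray(active_edges, dtype=bool)
        axial_terms = axial_terms[active_edges]
        node_ok = active_edges[:-1] & active_edges[1:]
        bend_terms = bend_terms[node_ok]
        twist_terms = twist_terms[node_ok]
    return float(axial_terms.sum() + bend_terms.sum() + twist_terms.sum())


def _grad_kernel(
    verts, phi, U, V, lbar_e, lbar_v, kbar, taubar, b, beta, alpha_abs,
    edge_act, grad_e, G,
):
    """Scalar-loop energy gradient w.r.t. edge vectors and frame angles.

    Writes the per-edge vector gradient into ``grad_e`` and the angle
    gradient into ``G``.  Mirrors the vectorized formulas in
    :func:`grad_energy`; kept loop-shaped so it can be jitted.
    """
    n_e = len(phi)
    # tangents and lengths
    lens = np.empty(n_e)
    t = np.empty((n_e, 3))
    for j in range(n_e):
        ex = verts[j + 1, 0] - verts[j, 0]
        ey = verts[j + 1, 1] - verts[j, 1]
        ez = verts[j + 1, 2] - verts[j, 2]
        ln = (ex * ex + ey * ey + ez * ez) ** 0.5
        lens[j] = ln
        t[j, 0] = ex / ln
        t[j, 1] = ey / ln
        t[j, 2] = ez / ln
        # axial part
        s = ln / lbar_e[j] - 1.0
        if edge_act[j]:
            coef = alpha_abs * s
            grad_e[j, 0] += coef * t[j, 0]
            grad_e[j, 1] += coef * t[j, 1]
            grad_e[j, 2] += coef * t[j, 2]
    # directors
    d1 = np.empty((n_e, 3))
    d2 = np.empty((n_e, 3))
    for j in range(n_e):
        c = np.cos(phi[j])
        s = np.sin(phi[j])
        for k in range(3):
            d1[j, k] = c * U[j, k] + s * V[j, k]
            d2[j, k] = -s * U[j, k] + c * V[j, k]
    G_bend = np.zeros(n_e)
    for i in range(1, n_e):  # interior node i, edges i-1 and i
        if not (edge_act[i - 1] and edge_act[i]):
            continue
        dot = t[i - 1, 0] * t[i, 0] + t[i - 1, 1] * t[i, 1] + t[i - 1, 2] * t[i, 2]
        chi = 1.0 + dot
        kbx = 2.0 * (t[i - 1, 1] * t[i, 2] - t[i - 1, 2] * t[i, 1]) / chi
        kby = 2.0 * (t[i - 1, 2] * t[i, 0] - t[i - 1, 0] * t[i, 2]) / chi
        kbz = 2.0 * (t[i - 1, 0] * t[i, 1] - t[i - 1, 1] * t[i, 0]) / chi
        s1x = d1[i - 1, 0] + d1[i, 0]
        s1y = d1[i - 1, 1] + d1[i, 1]
        s1z = d1[i - 1, 2] + d1[i, 2]
        s2x = d2[i - 1, 0] + d2[i, 0]
        s2y = d2[i - 1, 1] + d2[i, 1]
        s2z = d2[i - 1, 2] + d2[i, 2]
        k1 = 0.5 * (s2x * kbx + s2y * kby + s2z * kbz)
        k2 = -0.5 * (s1x * kbx + s1y * kby + s1z * kbz)
        dk1 = k1 - kbar[i - 1, 0]
        dk2 = k2 - kbar[i - 1, 1]
        w1 = b * dk1 / lbar_v[i - 1]
        w2 = b * dk2 / lbar_v[i - 1]
        # tilde quantities
        ttx = (t[i - 1, 0] + t[i, 0]) / chi
        tty = (t[i - 1, 1] + t[i, 1]) / chi
        ttz = (t[i - 1, 2] + t[i, 2]) / chi
        td1x, td1y, td1z = s1x / chi, s1y / chi, s1z / chi
        td2x, td2y, td2z = s2x / chi, s2y / chi, s2z / chi
        # cross products t_i x tilde_d2, t_{i-1} x tilde_d2, etc.
        c_n_d2x = t[i, 1] * td2z - t[i, 2] * td2y
        c_n_d2y = t[i, 2] * td2x - t[i, 0] * td2z
        c_n_d2z = t[i, 0] * td2y - t[i, 1] * td2x
        c_p_d2x = t[i - 1, 1] * td2z - t[i - 1, 2] * td2y
        c_p_d2y = t[i - 1, 2] * td2x - t[i - 1, 0] * td2z
        c_p_d2z = t[i - 1, 0] * td2y - t[i - 1, 1] * td2x
        c_n_d1x = t[i, 1] * td1z - t[i, 2] * td1y
        c_n_d1y = t[i, 2] * td1x - t[i, 0] * td1z
        c_n_d1z = t[i, 0] * td1y - t[i, 1] * td1x
        c_p_d1x = t[i - 1, 1] * td1z - t[i - 1, 2] * td1y
        c_p_d1y = t[i - 1, 2] * td1x - t[i - 1, 0] * td1z
        c_p_d1z = t[i - 1, 0] * td1y - t[i - 1, 1] * td1x
        ilp = 1.0 / lens[i - 1]
        iln = 1.0 / lens[i]
        grad_e[i - 1, 0] += w1 * (-k1 * ttx + c_n_d2x) * ilp + w2 * (-k2 * ttx - c_n_d1x) * ilp
        grad_e[i - 1, 1] += w1 * (-k1 * tty + c_n_d2y) * ilp + w2 * (-k2 * tty - c_n_d1y) * ilp
        grad_e[i - 1, 2] += w1 * (-k1 * ttz + c_n_d2z) * ilp + w2 * (-k2 * ttz - c_n_d1z) * ilp
        grad_e[i, 0] += w1 * (-k1 * ttx - c_p_d2x) * iln + w2 * (-k2 * ttx + c_p_d1x) * iln
        grad_e[i, 1] += w1 * (-k1 * tty - c_p_d2y) * iln + w2 * (-k2 * tty + c_p_d1y) * iln
        grad_e[i, 2] += w1 * (-k1 * ttz - c_p_d2z) * iln + w2 * (-k2 * ttz + c_p_d1z) * iln
        # angle gradient, bending part
        c1_prev = -0.5 * (d1[i - 1, 0] * kbx + d1[i - 1, 1] * kby + d1[i - 1, 2] * kbz)
        c1_next = -0.5 * (d1[i, 0] * kbx + d1[i, 1] * kby + d1[i, 2] * kbz)
        c2_prev = -0.5 * (d2[i - 1, 0] * kbx + d2[i - 1, 1] * kby + d2[i - 1, 2] * kbz)
        c2_next = -0.5 * (d2[i, 0] * kbx + d2[i, 1] * kby + d2[i, 2] * kbz)
        G_bend[i - 1] += w1 * c1_prev + w2 * c2_prev
        G_bend[i] += w1 * c1_next + w2 * c2_next
        # twist part of the angle gradient
        tau = phi[i] - phi[i - 1]
        tau = (tau + np.pi) % (2.0 * np.pi) - np.pi
        if tau == -np.pi:
            tau = np.pi
        wt = beta * (tau - taubar[i - 1]) / lbar_v[i - 1]
        G[i] += wt
        G[i - 1] -= wt
    for j in range(n_e):
        G[j] += G_bend[j]
    # holonomy coupling: suffix sums of the bending angle gradient
    W = 0.0
    for i in range(n_e - 1, 0, -1):
        W += G_bend[i]
        if not (edge_act[i - 1] and edge_act[i]):
            continue
        dot = t[i - 1, 0] * t[i, 0] + t[i - 1, 1] * t[i, 1] + t[i - 1, 2] * t[i, 2]
        chi = 1.0 + dot
        kbx = 2.0 * (t[i - 1, 1] * t[i, 2] - t[i - 1, 2] * t[i, 1]) / chi
        kby = 2.0 * (t[i - 1, 2] * t[i, 0] - t[i - 1, 0] * t[i, 2]) / chi
        kbz = 2.0 * (t[i - 1, 0] * t[i, 1] - t[i - 1, 1] * t[i, 0]) / chi
        cp = W / (2.0 * lens[i - 1])
        cn = W / (2.0 * lens[i])
        grad_e[i - 1, 0] -= cp * kbx
        grad_e[i - 1, 1] -= cp * kby
        grad_e[i - 1, 2] -= cp * kbz
        grad_e[i, 0] -= cn * kbx
        grad_e[i, 1] -= cn * kby
        grad_e[i, 2] -= cn * kbz


try:
    from numba import njit as _njit_grad

    _grad_kernel = _njit_grad(cache=True)(_grad_kernel)
    _HAVE_NUMBA_GRAD = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA_GRAD = False


def grad_energy(
    state: RodState,
    natural: NaturalShape,
    spec: CoilSpec,
    active_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`total_energy`.

    Returns ``(grad_X, grad_Phi)`` with shapes ``(N, 3)`` and ``(N-1,)``.

    The vertex gradient has three contributions: the axial part, the
    explicit bending part through the curvature binormal with the frames
    varying by adapted parallel transport, and the twist/holonomy part.
    The latter arises because displacing a vertex rotates every downstream
    parallel-transported frame about its tangent by the holonomy increment
    ``psi_i`` with gradients ``grad_{e^{i-1}} psi_i = (kb)_i / (2|e^{i-1}|)``
    and ``grad_{e^i} psi_i = (kb)_i / (2|e^i|)``; it couples to the energy
    through the suffix sums of the frame-angle gradient.  Free ends need no
    special treatment ("do nothing"): end nodes simply carry no bending or
    twist terms.
    """
    _check_sizes(state, natural)
    n = state.n_vertices
    b = spec.bend_stiffness
    beta = spec.twist_stiffness
    alpha_abs = spec.axial_penalty

    e = state.edges
    lengths = np.linalg.norm(e, axis=1)
    t = e / lengths[:, None]
    lbar_e = natural.rest_edge_lengths
    lbar_v = natural.voronoi_lengths

    if active_edges is None:
        edge_act = np.ones(n - 1, dtype=bool)
    else:
        edge_act = np.asarray(active_edges, dtype=bool)
    node_act = edge_act[:-1] & edge_act[1:]  # interior nodes 1..N-2

    if _HAVE_NUMBA_GRAD:
        dots = np.sum(t[:-1] * t[1:], axis=1)
        if np.any(dots <= -1.0 + _EPS_ANTIPARALLEL):
            raise DegenerateTurnError(
                "antiparallel consecutive tangents (180 degree kink)"
            )
        grad_e = np.zeros((n - 1, 3))
        G = np.zeros(n - 1)
        _grad_kernel(
            np.ascontiguousarray(state.vertices),
            np.ascontiguousarray(state.edge_angles),
            np.ascontiguousarray(state.bishop_U),
            np.ascontiguousarray(state.bishop_V),
            np.ascontiguousarray(lbar_e),
            np.ascontiguousarray(lbar_v),
            np.ascontiguousarray(natural.natural_curvatures),
            np.ascontiguousarray(natural.natural_twist),
            b,
            beta,
            alpha_abs,
            edge_act,
            grad_e,
            G,
        )
        grad_X = np.zeros((n, 3))
        grad_X[:-1] -= grad_e
        grad_X[1:] += grad_e
        return grad_X, G

    d1, d2 = material_directors(state)
    dots = np.sum(t[:-1] * t[1:], axis=1)
    if np.any(dots <= -1.0 + _EPS_ANTIPARALLEL):
        raise DegenerateTurnError("antiparallel consecutive tangents (180 degree kink)")
    chi = 1.0 + dots
    kb = 2.0 * np.cross(t[:-1], t[1:]) / chi[:, None]

    kappa = discrete_curvatures(state)
    dk = (kappa - natural.natural_curvatures) * node_act[:, None]
    tau = measure_twist(state)
    dtau = (tau - natural.natural_twist) * node_act

    # --- gradient with respect to edge vectors --------------------------
    grad_e = np.zeros((n - 1, 3))

    # axial part
    strain = lengths / lbar_e - 1.0
    grad_e += (alpha_abs * strain * edge_act)[:, None] * t

    # bending part: adapted-frame curvature gradients (tilde formulas)
    tilde_t = (t[:-1] + t[1:]) / chi[:, None]
    tilde_d1 = (d1[:-1] + d1[1:]) / chi[:, None]
    tilde_d2 = (d2[:-1] + d2[1:]) / chi[:, None]
    w1 = (b * dk[:, 0] / lbar_v)[:, None]  # dE/dkappa_1 per node
    w2 = (b * dk[:, 1] / lbar_v)[:, None]
    # node i couples to edges i-1 and i
    gk1_prev = (-kappa[:, 0][:, None] * tilde_t + np.cross(t[1:], tilde_d2)) / lengths[:-1][:, None]
    gk1_next = (-kappa[:, 0][:, None] * tilde_t - np.cross(t[:-1], tilde_d2)) / lengths[1:][:, None]
    gk2_prev = (-kappa[:, 1][:, None] * tilde_t - np.cross(t[1:], tilde_d1)) / lengths[:-1][:, None]
    gk2_next = (-kappa[:, 1][:, None] * tilde_t + np.cross(t[:-1], tilde_d1)) / lengths[1:][:, None]
    grad_e[:-1] += w1 * gk1_prev + w2 * gk2_prev
    grad_e[1:] += w1 * gk1_next + w2 * gk2_next

    # --- gradient with respect to frame angles --------------------------
    # dE/d(theta^j) where theta^j rotates the material frame of edge j
    # about its tangent; this is also the Phi-gradient.
    # per-node curvature coupling: d kappa_i1 / d theta^j = -1/2 d1^j . kb_i
    # for j in {i-1, i}; d kappa_i2 / d theta^j = -1/2 d2^j . kb_i.
    c1_prev = -0.5 * np.sum(d1[:-1] * kb, axis=1)
    c1_next = -0.5 * np.sum(d1[1:] * kb, axis=1)
    c2_prev = -0.5 * np.sum(d2[:-1] * kb, axis=1)
    c2_next = -0.5 * np.sum(d2[1:] * kb, axis=1)
    G_bend = np.zeros(n - 1)
    wb1 = b * dk[:, 0] / lbar_v
    wb2 = b * dk[:, 1] / lbar_v
    G_bend[:-1] += wb1 * c1_prev + wb2 * c2_prev
    G_bend[1:] += wb1 * c1_next + wb2 * c2_next
    # twist part: tau^j = phi^j - phi^{j-1} for interior edges.  Note the
    # twist energy depends on Phi only (the Bishop reference is twist-free
    # for every centerline), so it enters the Phi-gradient but not the
    # holonomy coupling below.
    G = G_bend.copy()
    wt = beta * dtau / lbar_v
    G[1:] += wt
    G[:-1] -= wt

    # --- holonomy coupling into the vertex gradient ---------------------
    # rotating frames j..N-2 by the holonomy increment psi_i (node i)
    # changes the bending energy by W_i = sum_{j >= i} G_bend_j; the
    # holonomy increment has edge gradients -(kb)_i / (2|e|) on both
    # incident edges (sign certified against the finite-difference oracle)
    W = np.cumsum(G_bend[::-1])[::-1]  # suffix sums, W[j] = sum_{k>=j} G_bend_k
    Wn = W[1:]  # node i=1..N-2 rotates frames i..N-2
    coeff_prev = Wn / (2.0 * lengths[:-1])
    coeff_next = Wn / (2.0 * lengths[1:])
    grad_e[:-1] -= coeff_prev[:, None] * kb
    grad_e[1:] -= coeff_next[:, None] * kb

    # --- scatter edge gradients to vertices -----------------------------
    grad_X = np.zeros((n, 3))
    grad_X[:-1] -= grad_e
    grad_X[1:] += grad_e
    return grad_X, G
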