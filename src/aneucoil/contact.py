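"""Octree-accelerated contact detection and penalty/friction forces.

Contacts come in two families: coil-coil (edge segment vs edge segment)
and coil-wall (node vs surface triangle; the micro-catheter tube is just
another wall).  Detection is two-phase: an octree broad phase returning a
superset of candidates, then exact minimum distances (Lumelsky for
segment pairs, closest-feature for point-triangle).  Forces are penalty
normal forces with velocity dissipation plus Coulomb friction: slip-only
for coil-coil, stick-slip for coil-wall.

Force units are mN (kg mm / s^2), lengths mm, velocities mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Octree",
    "ContactSet",
    "FrictionParams",
    "WallSurface",
    "candidate_pairs_coil",
    "min_distance_segments",
    "detect_coil_collisions",
    "detect_wall_collisions",
    "coil_coil_normal_force",
    "wall_normal_force",
    "coil_coil_friction",
    "wall_friction",
    "assemble_external_forces",
]


# ---------------------------------------------------------------------------
# octree
# ---------------------------------------------------------------------------


class Octree:
    """Axis-aligned octree over a point set (edge or triangle centers).

    Built level by level with vectorized binning: cells holding more than
    ``leaf_capacity`` points are split until ``max_depth``.  Every item is
    indexed in exactly one leaf.  ``query(point, radius)`` returns a
    superset of all items within ``radius`` of ``point``.
    """

    def __init__(self, points: np.ndarray, leaf_capacity: int = 8, max_depth: int = 12):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must be (M, 3)")
        self.points = points
        self.leaf_capacity = int(leaf_capacity)
        self.max_depth = int(max_depth)
        if len(points) == 0:
            points = points.reshape(0, 3)
            lo = np.zeros(3)
            hi = np.ones(3)
        else:
            lo = points.min(axis=0)
            hi = points.max(axis=0)
        size = float(max((hi - lo).max(), 1e-9)) * (1.0 + 1e-9)
        self.root_origin = lo
        self.root_size = size

        n = len(points)
        active = np.arange(n)
        centers_parts: list[np.ndarray] = []
        halves_parts: list[np.ndarray] = []
        items_parts: list[np.ndarray] = []
        counts_parts: list[np.ndarray] = []
        for depth in range(1, self.max_depth + 1):
            if len(active) == 0:
                break
            cell = size / (1 << depth)
            ic = np.floor((points[active] - lo) / cell).astype(np.int64)
            np.clip(ic, 0, (1 << depth) - 1, out=ic)
            key = (ic[:, 0] << (2 * depth)) | (ic[:, 1] << depth) | ic[:, 2]
            order = np.argsort(key, kind="stable")
            skey = key[order]
            sact = active[order]
            sic = ic[order]
            bounds = np.flatnonzero(np.diff(skey)) + 1
            starts = np.concatenate([[0], bounds])
            counts = np.diff(np.concatenate([starts, [len(skey)]]))
            is_leaf = (counts <= self.leaf_capacity) | (depth == self.max_depth)
            pt_leaf = np.repeat(is_leaf, counts)
            leaf_groups = np.flatnonzero(is_leaf)
            if len(leaf_groups):
                centers_parts.append(lo + (sic[starts[leaf_groups]] + 0.5) * cell)
                halves_parts.append(np.full(len(leaf_groups), cell / 2.0))
                items_parts.append(sact[pt_leaf])
                counts_parts.append(counts[leaf_groups])
            active = sact[~pt_leaf]
        if not centers_parts:
            centers_parts = [lo[None, :]]
            halves_parts = [np.array([size / 2.0])]
            items_parts = [np.empty(0, dtype=np.int64)]
            counts_parts = [np.array([0], dtype=np.int64)]
        self.leaf_centers = np.concatenate(centers_parts, axis=0)
        self.leaf_halves = np.concatenate(halves_parts)
        self._counts = np.concatenate(counts_parts).astype(np.int64)
        self._starts = np.concatenate([[0], np.cumsum(self._counts)[:-1]])
        self._items = np.concatenate(items_parts)
        self._center_sq = np.einsum("ij,ij->i", self.leaf_centers, self.leaf_centers)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_centers)

    def leaf_item_lists(self) -> list[np.ndarray]:
        return [
            self._items[s : s + c] for s, c in zip(self._starts, self._counts)
        ]

    def query(self, point: np.ndarray, radius: float) -> np.ndarray:
        """Indices of all items in leaves intersecting the query ball."""
        q, items = self.query_batch(np.asarray(point, dtype=float)[None, :], radius)
        return items

    def query_batch(self, points: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized ball query for many points.

        Returns ``(query_idx, item_idx)`` pairs such that the leaf of
        ``item_idx`` intersects the ball around ``points[query_idx]``;
        a guaranteed superset of all true within-radius pairs.
        """
        points = np.asarray(points, dtype=float)
        # leaf accepted if the ball reaches the leaf's bounding sphere
        reach = radius + self.leaf_halves * np.sqrt(3.0)
        p_sq = np.einsum("ij,ij->i", points, points)
        d2 = p_sq[:, None] + self._center_sq[None, :] - 2.0 * (points @ self.leaf_centers.T)
        qi, li = np.nonzero(d2 <= reach[None, :] ** 2)
        if len(qi) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        c = self._counts[li]
        total = int(c.sum())
        q_rep = np.repeat(qi, c)
        cum = np.cumsum(c) - c
        offs = np.arange(total, dtype=np.int64) - np.repeat(cum, c)
        item_pos = np.repeat(self._starts[li], c) + offs
        return q_rep, self._items[item_pos]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FrictionParams:
    """Contact spring/dissipation constants and Coulomb coefficients.

    ``k_sc``/``gamma_sc`` act on coil-coil pairs (applied to the raw
    minimum-distance vector, so k has units mN/mm^2), ``k_w``/``gamma_w``
    on walls (unit-normal form, mN/mm).  The stick threshold ``v_eps`` is
    in mm/s.
    """

    k_sc: float = 100.0
    gamma_sc: float = 1.0
    k_w: float = 30.0
    gamma_w: float = 1.0e-2
    mu_slip_cc: float = 0.4
    mu_slip_cw: float = 0.4
    mu_stick_cw: float = 0.6
    v_eps: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.mu_stick_cw < self.mu_slip_cw:
            raise ValueError("mu_stick_cw must be >= mu_slip_cw")


@dataclass
class ContactSet:
    """Detected contacts for one configuration.

    Edge-edge arrays are aligned (one row per contact pair); likewise the
    node-triangle arrays.
    """

    ee_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ee_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ee_dvec: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    ee_dist: np.ndarray = field(default_factory=lambda: np.empty(0))
    ee_eps: np.ndarray = field(default_factory=lambda: np.empty(0))
    ee_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    ee_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    nt_node: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    nt_tri: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    nt_dist: np.ndarray = field(default_factory=lambda: np.empty(0))
    nt_point: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    nt_normal: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def n_edge_pairs(self) -> int:
        return len(self.ee_i)

    @property
    def n_wall(self) -> int:
        return len(self.nt_node)


class WallSurface:
    """Static triangulated obstacle (vessel wall or catheter tube).

    Holds per-triangle geometry and a one-time octree over triangle
    centers; per-triangle ``r_ST`` is the radius of the smallest sphere
    around the triangle center containing the triangle.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, normals: np.ndarray | None = None):
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        self.tri = vertices[faces]  # (M, 3, 3)
        self.centers = self.tri.mean(axis=1)
        self.r_st = np.linalg.norm(self.tri - self.centers[:, None, :], axis=2).max(axis=1)
        if normals is None:
            n = np.cross(self.tri[:, 1] - self.tri[:, 0], self.tri[:, 2] - self.tri[:, 0])
            ln = np.linalg.norm(n, axis=1)
            ln[ln == 0] = 1.0
            normals = n / ln[:, None]
        self.normals = np.asarray(normals, dtype=float)
        self.octree = Octree(self.centers)

    @classmethod
    def from_trimesh(cls, mesh) -> "WallSurface":
        return cls(mesh.vertices, mesh.faces, np.asarray(mesh.face_normals, dtype=float))

    @property
    def n_triangles(self) -> int:
        return len(self.centers)


# ---------------------------------------------------------------------------
# narrow-phase primitives
# ---------------------------------------------------------------------------


def _segment_pairs_kernel(p1, d1, p2, d2, s_out, t_out):
    """Scalar-loop closest segment parameters (jitted when available)."""
    for i in range(len(s_out)):
        ax, ay, az = d1[i, 0], d1[i, 1], d1[i, 2]
        bx, by, bz = d2[i, 0], d2[i, 1], d2[i, 2]
        rx = p1[i, 0] - p2[i, 0]
        ry = p1[i, 1] - p2[i, 1]
        rz = p1[i, 2] - p2[i, 2]
        a = ax * ax + ay * ay + az * az
        e = bx * bx + by * by + bz * bz
        f = bx * rx + by * ry + bz * rz
        c = ax * rx + ay * ry + az * rz
        b = ax * bx + ay * by + az * bz
        denom = a * e - b * b
        if denom > 1e-14 * a * e + 1e-300:
            s = (b * f - c * e) / denom
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
        else:
            s = 0.0
        t = (b * s + f) / e if e > 0.0 else 0.0
        if t < 0.0:
            t = 0.0
            s = -c / a if a > 0.0 else 0.0
            s = min(max(s, 0.0), 1.0)
        elif t > 1.0:
            t = 1.0
            s = (b - c) / a if a > 0.0 else 0.0
            s = min(max(s, 0.0), 1.0)
        s_out[i] = s
        t_out[i] = t


def _point_triangle_kernel(points, tri, out):
    """Scalar-loop closest point on triangle (Ericson region walk)."""
    for i in range(len(points)):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        ax, ay, az = tri[i, 0, 0], tri[i, 0, 1], tri[i, 0, 2]
        bx, by, bz = tri[i, 1, 0], tri[i, 1, 1], tri[i, 1, 2]
        cx, cy, cz = tri[i, 2, 0], tri[i, 2, 1], tri[i, 2, 2]
        abx, aby, abz = bx - ax, by - ay, bz - az
        acx, acy, acz = cx - ax, cy - ay, cz - az
        apx, apy, apz = px - ax, py - ay, pz - az
        d1 = abx * apx + aby * apy + abz * apz
        d2 = acx * apx + acy * apy + acz * apz
        if d1 <= 0.0 and d2 <= 0.0:
            out[i, 0], out[i, 1], out[i, 2] = ax, ay, az
            continue
        bpx, bpy, bpz = px - bx, py - by, pz - bz
        d3 = abx * bpx + aby * bpy + abz * bpz
        d4 = acx * bpx + acy * bpy + acz * bpz
        if d3 >= 0.0 and d4 <= d3:
            out[i, 0], out[i, 1], out[i, 2] = bx, by, bz
            continue
        vc = d1 * d4 - d3 * d2
        if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
            v = d1 / (d1 - d3)
            out[i, 0] = ax + v * abx
            out[i, 1] = ay + v * aby
            out[i, 2] = az + v * abz
            continue
        cpx, cpy, cpz = px - cx, py - cy, pz - cz
        d5 = abx * cpx + aby * cpy + abz * cpz
        d6 = acx * cpx + acy * cpy + acz * cpz
        if d6 >= 0.0 and d5 <= d6:
            out[i, 0], out[i, 1], out[i, 2] = cx, cy, cz
            continue
        vb = d5 * d2 - d1 * d6
        if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
            w = d2 / (d2 - d6)
            out[i, 0] = ax + w * acx
            out[i, 1] = ay + w * acy
            out[i, 2] = az + w * acz
            continue
        va = d3 * d6 - d5 * d4
        if va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
            w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
            out[i, 0] = bx + w * (cx - bx)
            out[i, 1] = by + w * (cy - by)
            out[i, 2] = bz + w * (cz - bz)
            continue
        denom = 1.0 / (va + vb + vc)
        v = vb * denom
        w = vc * denom
        out[i, 0] = ax + v * abx + w * acx
        out[i, 1] = ay + v * aby + w * acy
        out[i, 2] = az + v * abz + w * acz


try:
    from numba import njit as _njit_contact

    _segment_pairs_kernel = _njit_contact(cache=True)(_segment_pairs_kernel)
    _point_triangle_kernel = _njit_contact(cache=True)(_point_triangle_kernel)
    _HAVE_NUMBA_CONTACT = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA_CONTACT = False


def _segment_pairs_closest(p1, d1, p2, d2):
    """Vectorized Lumelsky closest points between segment batches.

    Segments are ``p + s*d`` with ``s`` in [0, 1].  Returns ``(s, t)``.
    """
    if _HAVE_NUMBA_CONTACT:
        m = len(p1)
        s_out = np.empty(m)
        t_out = np.empty(m)
        _segment_pairs_kernel(
            np.ascontiguousarray(p1), np.ascontiguousarray(d1),
            np.ascontiguousarray(p2), np.ascontiguousarray(d2),
            s_out, t_out,
        )
        return s_out, t_out
    return _segment_pairs_closest_numpy(p1, d1, p2, d2)


def _segment_pairs_closest_numpy(p1, d1, p2, d2):
    r = p1 - p2
    a = np.sum(d1 * d1, axis=1)
    e = np.sum(d2 * d2, axis=1)
    f = np.sum(d2 * r, axis=1)
    c = np.sum(d1 * r, axis=1)
    b = np.sum(d1 * d2, axis=1)
    denom = a * e - b * b
    s = np.where(denom > 1e-14 * a * e + 1e-300, (b * f - c * e), 0.0)
    s = np.where(denom > 1e-14 * a * e + 1e-300, s / np.where(denom == 0, 1.0, denom), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = (b * s + f) / np.where(e == 0, 1.0, e)
    t_cl = np.clip(t, 0.0, 1.0)
    recl = t_cl != t
    s = np.where(recl, np.clip((b * t_cl - c) / np.where(a == 0, 1.0, a), 0.0, 1.0), s)
    return s, t_cl


def min_distance_segments(p1, q1, p2, q2):
    """Exact minimum distance between closed segments [p1,q1] and [p2,q2].

    Returns ``(distance, d_vec, (s, t))`` where ``d_vec`` points from the
    closest point on segment 1 to the closest point on segment 2 and
    ``s, t`` are the barycentric parameters of the closest points.
    """
    p1 = np.asarray(p1, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    d1 = q1 - p1
    d2 = q2 - p2
    if np.dot(d1, d1) == 0.0 or np.dot(d2, d2) == 0.0:
        raise ValueError("degenerate (zero-length) segment")
    s, t = _segment_pairs_closest(p1[None], d1[None], p2[None], d2[None])
    c1 = p1 + s[0] * d1
    c2 = p2 + t[0] * d2
    dvec = c2 - c1
    return float(np.linalg.norm(dvec)), dvec, (float(s[0]), float(t[0]))


def _point_triangle_closest(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle for point batches (Ericson)."""
    if _HAVE_NUMBA_CONTACT:
        out = np.empty((len(points), 3))
        _point_triangle_kernel(
            np.ascontiguousarray(points), np.ascontiguousarray(tri), out
        )
        return out
    return _point_triangle_closest_numpy(points, tri)


def _point_triangle_closest_numpy(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a
    d1 = np.sum(ab * ap, axis=1)
    d2 = np.sum(ac * ap, axis=1)
    bp = points - b
    d3 = np.sum(ab * bp, axis=1)
    d4 = np.sum(ac * bp, axis=1)
    cp = points - c
    d5 = np.sum(ab * cp, axis=1)
    d6 = np.sum(ac * cp, axis=1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom_f = va + vb + vc
    denom_f = np.where(denom_f == 0.0, 1.0, denom_f)
    v_face = vb / denom_f
    w_face = vc / denom_f
    out = a + v_face[:, None] * ab + w_face[:, None] * ac

    # edge AC region
    w_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0, 1.0)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond_ac[:, None], a + w_ac[:, None] * ac, out)
    # edge BC region
    num_bc = d4 - d3
    den_bc = (d4 - d3) + (d5 - d6)
    w_bc = np.clip(num_bc / np.where(den_bc == 0, 1.0, den_bc), 0.0, 1.0)
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(cond_bc[:, None], b + w_bc[:, None] * (c - b), out)
    # edge AB region
    v_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0, 1.0)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond_ab[:, None], a + v_ab[:, None] * ab, out)
    # vertex regions
    out = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, out)
    return out


def _point_triangle_project(points: np.ndarray, tri: np.ndarray, normals: np.ndarray):
    """In-plane projection and containment test (literal narrow phase)."""
    a = tri[:, 0]
    h = np.sum((points - a) * normals, axis=1)
    proj = points - h[:, None] * normals
    # barycentric containment
    v0 = tri[:, 1] - a
    v1 = tri[:, 2] - a
    v2 = proj - a
    d00 = np.sum(v0 * v0, axis=1)
    d01 = np.sum(v0 * v1, axis=1)
    d11 = np.sum(v1 * v1, axis=1)
    d20 = np.sum(v2 * v0, axis=1)
    d21 = np.sum(v2 * v1, axis=1)
    den = d00 * d11 - d01 * d01
    den = np.where(den == 0, 1.0, den)
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    inside = (v >= -1e-12) & (w >= -1e-12) & (v + w <= 1.0 + 1e-12)
    return proj, np.abs(h), inside


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def broad_phase_radius(rest_length: float, D2: float) -> float:
    """Broad-phase neighborhood radius sqrt((l_bar/2)^2 + D2^2)."""
    return float(np.sqrt((rest_length / 2.0) ** 2 + D2**2))


def filter_pairs_center_condition(
    vertices: np.ndarray, pairs: np.ndarray, rest_length: float, D2: float
) -> np.ndarray:
    """Exact center-distance necessary condition applied to given pairs."""
    if len(pairs) == 0:
        return pairs
    centers = 0.5 * (vertices[:-1] + vertices[1:])
    radius = broad_phase_radius(rest_length, D2)
    d2c = np.sum((centers[pairs[:, 1]] - centers[pairs[:, 0]]) ** 2, axis=1)
    return pairs[d2c <= radius**2]


def candidate_pairs_coil(
    state,
    octree: Octree | None = None,
    rest_length: float | None = None,
    D2: float = 0.305,
    active_edges: np.ndarray | None = None,
    extra_radius: float = 0.0,
) -> np.ndarray:
    """Broad-phase candidate edge pairs for coil self-collision.

    Returns an array of pairs ``(i, j)`` with ``i < j``, excluding
    adjacent edges (sharing a vertex) and virtual edges, satisfying the
    center-distance necessary condition
    ``||c_j - c_i|| <= sqrt((l_bar/2)^2 + D2^2)``.
    """
    verts = state.vertices
    centers = 0.5 * (verts[:-1] + verts[1:])
    if rest_length is None:
        rest_length = float(np.mean(state.edge_lengths))
    radius = broad_phase_radius(rest_length, D2) + extra_radius
    if octree is None:
        octree = Octree(centers)
    qi, it = octree.query_batch(centers, radius)
    mask = it > qi + 1  # unordered pairs, non-adjacent
    i, j = qi[mask], it[mask]
    if active_edges is not None:
        act = np.asarray(active_edges, dtype=bool)
        keep = act[i] & act[j]
        i, j = i[keep], j[keep]
    d2c = np.sum((centers[j] - centers[i]) ** 2, axis=1)
    keep = d2c <= radius**2
    return np.column_stack([i[keep], j[keep]])


def detect_coil_collisions(
    state,
    octree: Octree | None = None,
    D2: float = 0.305,
    rest_length: float | None = None,
    active_edges: np.ndarray | None = None,
    pairs: np.ndarray | None = None,
) -> ContactSet:
    """Narrow-phase coil self-collisions: keep pairs with the exact
    segment distance ``d_min <= D2``; overlap ``eps = D2 - d_min``."""
    if pairs is None:
        pairs = candidate_pairs_coil(state, octree, rest_length, D2, active_edges)
    cs = ContactSet()
    if len(pairs) == 0:
        return cs
    v = state.vertices
    i, j = pairs[:, 0], pairs[:, 1]
    p1 = v[i]
    d1 = v[i + 1] - v[i]
    p2 = v[j]
    d2v = v[j + 1] - v[j]
    s, t = _segment_pairs_closest(p1, d1, p2, d2v)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2v
    dvec = c2 - c1
    dist = np.linalg.norm(dvec, axis=1)
    hit = dist <= D2
    cs.ee_i = i[hit]
    cs.ee_j = j[hit]
    cs.ee_dvec = dvec[hit]
    cs.ee_dist = dist[hit]
    cs.ee_eps = D2 - dist[hit]
    cs.ee_s = s[hit]
    cs.ee_t = t[hit]
    return cs


def detect_wall_collisions(
    points: np.ndarray,
    wall: WallSurface,
    D2: float,
    node_indices: np.ndarray | None = None,
    literal_projection: bool = False,
    candidates: tuple[np.ndarray, np.ndarray] | None = None,
) -> ContactSet:
    """Node-vs-wall collisions.

    Broad phase: octree query with radius ``D2/2 + r_ST`` (per-triangle
    enclosing-sphere radius).  Narrow phase: closest point on the triangle
    (closest-feature by default; with ``literal_projection`` only in-plane
    projections falling inside the triangle count, which can let nodes
    tunnel through mesh edges but reproduces the stated rule).  Contact if
    the distance is at most ``D2/2``.
    """
    points = np.asarray(points, dtype=float)
    if node_indices is None:
        node_indices = np.arange(len(points))
    cs = ContactSet()
    if candidates is None:
        radius = D2 / 2.0 + float(wall.r_st.max()) if wall.n_triangles else D2
        qi, ti = wall.octree.query_batch(points, radius)
        if len(qi) == 0:
            return cs
        # per-pair broad-phase inequality
        keep = (
            np.linalg.norm(points[qi] - wall.centers[ti], axis=1)
            <= D2 / 2.0 + wall.r_st[ti]
        )
        qi, ti = qi[keep], ti[keep]
    else:
        qi, ti = candidates
    if len(qi) == 0:
        return cs
    tri = wall.tri[ti]
    nrm = wall.normals[ti]
    if literal_projection:
        closest, dist, inside = _point_triangle_project(points[qi], tri, nrm)
        hit = inside & (dist <= D2 / 2.0)
    else:
        closest = _point_triangle_closest(points[qi], tri)
        dist = np.linalg.norm(points[qi] - closest, axis=1)
        hit = dist <= D2 / 2.0
    if not np.any(hit):
        return cs
    qi, ti = qi[hit], ti[hit]
    dist = dist[hit]
    closest = closest[hit]
    nrm = nrm[hit]
    # a node may hit several triangles; keep only its closest one to avoid
    # double-counting reaction forces on mesh creases
    order = np.lexsort((dist, qi))
    qi_s = qi[order]
    first = np.concatenate([[True], qi_s[1:] != qi_s[:-1]])
    sel = order[first]
    cs.nt_node = node_indices[qi[sel]]
    cs.nt_tri = ti[sel]
    cs.nt_dist = dist[sel]
    cs.nt_point = closest[sel]
    cs.nt_normal = nrm[sel]
    return cs


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def coil_coil_normal_force(
    eps: np.ndarray,
    dvec: np.ndarray,
    rel_vel: np.ndarray,
    params: FrictionParams,
) -> np.ndarray:
    """Penalty + dissipation normal force on the first edge of each pair.

    ``F = -H(eps) (k_sc eps + gamma_sc (v_1 - v_2) . d_min) d_min`` with
    the raw minimum-distance vector ``d_min`` pointing from the contact
    point on edge 1 to the one on edge 2; the partner edge receives the
    opposite force.
    """
    act = (eps > 0.0).astype(float)
    mag = params.k_sc * eps + params.gamma_sc * np.sum(rel_vel * dvec, axis=1)
    return -(act * mag)[:, None] * dvec


def coil_coil_friction(
    rel_vel: np.ndarray,
    dvec: np.ndarray,
    normal_force_mag: np.ndarray,
    params: FrictionParams,
    dv_cap: float | None = None,
) -> np.ndarray:
    """Slip-only Coulomb friction for coil-coil contacts.

    ``F = -mu_slip_cc ||F_perp|| v_par / ||v_par||``; zero when the
    relative tangential velocity vanishes (no stick branch is defined for
    self-contact).  ``dv_cap`` (mass over time step) optionally limits
    the magnitude so one explicit step cannot reverse the relative
    tangential velocity, which would otherwise ring at the step scale.
    """
    d2 = np.sum(dvec * dvec, axis=1)
    d2 = np.where(d2 == 0.0, 1.0, d2)
    v_par = rel_vel - (np.sum(rel_vel * dvec, axis=1) / d2)[:, None] * dvec
    speed = np.linalg.norm(v_par, axis=1)
    mag = params.mu_slip_cc * normal_force_mag
    if dv_cap is not None:
        mag = np.minimum(mag, dv_cap * speed)
    ok = speed > 1e-14
    scale = np.where(ok, mag / np.where(ok, speed, 1.0), 0.0)
    return -scale[:, None] * v_par


def wall_normal_force(
    eps: np.ndarray,
    normals: np.ndarray,
    node_force: np.ndarray,
    node_vel: np.ndarray,
    params: FrictionParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Wall reaction ``F = -H(eps) (||F_perp|| + k_w eps + gamma_w v.n) n``.

    ``F_perp`` is the wall-normal, wall-pressing part of the node's
    elastic + coil-coil force.  Returns ``(force, f_perp_mag)`` with the
    pressing magnitude used by the friction cap.
    """
    act = (eps > 0.0).astype(float)
    f_n = np.sum(node_force * normals, axis=1)
    f_perp = np.maximum(f_n, 0.0)
    v_n = np.sum(node_vel * normals, axis=1)
    mag = f_perp + params.k_w * eps + params.gamma_w * v_n
    return -(act * mag)[:, None] * normals, f_perp


def wall_friction(
    normals: np.ndarray,
    node_force: np.ndarray,
    node_vel: np.ndarray,
    f_perp_mag: np.ndarray,
    params: FrictionParams,
    dv_cap: float | None = None,
) -> np.ndarray:
    """Stick-slip Coulomb friction against a wall.

    Below the velocity threshold ``v_eps`` the tangential force is
    cancelled up to the stick cap ``mu_stick ||F_perp||``; above it,
    kinetic friction ``mu_slip ||F_perp||`` opposes the tangential
    velocity.  ``dv_cap`` (mass over time step) optionally limits the
    slip force so one explicit step cannot reverse the sliding velocity.
    """
    f_n = np.sum(node_force * normals, axis=1)
    f_par = node_force - f_n[:, None] * normals
    f_par_mag = np.linalg.norm(f_par, axis=1)
    v_n = np.sum(node_vel * normals, axis=1)
    v_par = node_vel - v_n[:, None] * normals
    v_par_mag = np.linalg.norm(v_par, axis=1)

    stick = v_par_mag <= params.v_eps
    out = np.zeros_like(node_force)
    # stick branch
    has_f = stick & (f_par_mag > 1e-14)
    cap = np.minimum(f_par_mag, params.mu_stick_cw * f_perp_mag)
    scale = np.where(has_f, cap / np.where(has_f, f_par_mag, 1.0), 0.0)
    out -= scale[:, None] * f_par
    # slip branch
    slip = ~stick
    mag = params.mu_slip_cw * f_perp_mag
    if dv_cap is not None:
        mag = np.minimum(mag, dv_cap * v_par_mag)
    scale_s = np.where(slip, mag / np.where(slip, v_par_mag, 1.0), 0.0)
    out -= scale_s[:, None] * v_par
    return out


@dataclass
class ContactDiagnostics:
    n_coil_pairs: int = 0
    n_wall: int = 0
    max_penetration: float = 0.0
    total_force_mag: float = 0.0
    max_friction_ratio: float = 0.0
    antisymmetry_residual: float = 0.0


def assemble_external_forces(
    state,
    walls: list[WallSurface],
    params: FrictionParams,
    D2: float,
    internal_force: np.ndarray,
    rest_length: float | None = None,
    active_edges: np.ndarray | None = None,
    active_nodes: np.ndarray | None = None,
    literal_projection: bool = False,
    dv_cap: float | None = None,
    coil_pairs: np.ndarray | None = None,
    wall_candidates: list | None = None,
) -> tuple[np.ndarray, ContactDiagnostics]:
    """Total contact force per node: coil-coil then wall/catheter terms.

    ``internal_force`` (the elastic force ``-grad_X E`` plus any body
    force) enters the wall reaction and friction through the
    tangential/normal decomposition.  Kinematic nodes (``active_nodes``
    False) and virtual edges are excluded from contact.
    """
    n = state.n_vertices
    verts = state.vertices
    vels = state.velocities
    F_cc = np.zeros((n, 3))
    diag = ContactDiagnostics()

    edge_act = np.ones(n - 1, dtype=bool) if active_edges is None else np.asarray(active_edges, bool).copy()
    if active_nodes is not None:
        nd = np.asarray(active_nodes, bool)
        edge_act &= nd[:-1] & nd[1:]
    else:
        nd = np.ones(n, dtype=bool)

    # --- coil-coil -------------------------------------------------------
    if coil_pairs is not None:
        # cached broad-phase superset: re-apply the exact center condition
        lr = rest_length if rest_length is not None else float(np.mean(state.edge_lengths))
        pairs = filter_pairs_center_condition(verts, coil_pairs, lr, D2)
        cset = detect_coil_collisions(state, D2=D2, pairs=pairs)
    else:
        cset = detect_coil_collisions(
            state, D2=D2, rest_length=rest_length, active_edges=edge_act
        )
    if cset.n_edge_pairs:
        i, j = cset.ee_i, cset.ee_j
        s, t = cset.ee_s, cset.ee_t
        v1 = (1 - s)[:, None] * vels[i] + s[:, None] * vels[i + 1]
        v2 = (1 - t)[:, None] * vels[j] + t[:, None] * vels[j + 1]
        rel = v1 - v2
        Fn = coil_coil_normal_force(cset.ee_eps, cset.ee_dvec, rel, params)
        fn_mag = np.linalg.norm(Fn, axis=1)
        Ff = coil_coil_friction(rel, cset.ee_dvec, fn_mag, params, dv_cap=dv_cap)
        Fpair = Fn + Ff
        # distribute to the four incident nodes by barycentric weights
        np.add.at(F_cc, i, (1 - s)[:, None] * Fpair)
        np.add.at(F_cc, i + 1, s[:, None] * Fpair)
        np.add.at(F_cc, j, -(1 - t)[:, None] * Fpair)
        np.add.at(F_cc, j + 1, -t[:, None] * Fpair)
        diag.n_coil_pairs = cset.n_edge_pairs
        diag.max_penetration = float(cset.ee_eps.max())
        with np.errstate(invalid="ignore"):
            fr = np.linalg.norm(Ff, axis=1) / np.where(fn_mag > 0, params.mu_slip_cc * fn_mag, np.inf)
        diag.max_friction_ratio = float(fr.max()) if len(fr) else 0.0

    F_total = F_cc.copy()
    node_force = internal_force + F_cc

    # --- walls (vessel + catheter tube) ----------------------------------
    act_ids = np.flatnonzero(nd)
    for w, wall in enumerate(walls):
        if wall_candidates is not None:
            qi, ti = wall_candidates[w]
            keep = nd[qi]
            ws = detect_wall_collisions(
                verts, wall, D2, literal_projection=literal_projection,
                candidates=(qi[keep], ti[keep]),
            )
        else:
            ws = detect_wall_collisions(
                verts[act_ids], wall, D2, node_indices=act_ids,
                literal_projection=literal_projection,
            )
        if ws.n_wall == 0:
            continue
        idx = ws.nt_node
        eps = D2 / 2.0 - ws.nt_dist
        Fw, f_perp = wall_normal_force(
            eps, ws.nt_normal, node_force[idx], vels[idx], params
        )
        Ffr = wall_friction(ws.nt_normal, node_force[idx], vels[idx], f_perp, params, dv_cap=dv_cap)
        np.add.at(F_total, idx, Fw + Ffr)
        diag.n_wall += ws.n_wall
        diag.max_penetration = max(diag.max_penetration, float(eps.max()))
        with np.errstate(invalid="ignore"):
            cap = max(params.mu_stick_cw, params.mu_slip_cw) * f_perp
            fr = np.linalg.norm(Ffr, axis=1) / np.where(cap > 0, cap, np.inf)
        diag.max_friction_ratio = max(diag.max_friction_ratio, float(fr.max()) if len(fr) else 0.0)

    diag.total_force_mag = float(np.linalg.norm(F_total, axis=1).sum())
    diag.antisymmetry_residual = float(np.linalg.norm(F_cc.sum(axis=0)))
    return F_total, diag
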