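"""Coil voxelization, region partitioning and occlusion classification.

A deployed coil (centerline polyline with diameter D2) is converted to a
binary occupancy field on a bounding cube: a voxel counts as coil when
its center lies in the swept volume (the union of segment capsules of
radius D2/2).  The aneurysm interior is split by a level set of the
signed distance function to the wall into a core and a boundary region
of equal volume, and a sphere at the neck probes the inflow zone.  The
resulting region-local packing densities feed a Raymond-Roy-type
classifier: class I (core, boundary and neck sphere all filled), II
(neck sphere empty), IIIa (core empty), IIIb (boundary empty) and Fail
(core and boundary empty: the coil has migrated into the parent vessel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from aneucoil.geometry import AneurysmDomain

__all__ = [
    "VoxelField",
    "RegionPartition",
    "OcclusionReport",
    "SweepResult",
    "mesh_sdf",
    "bounding_cube",
    "voxelize_coil",
    "partition_regions",
    "volume_fractions",
    "classify_rroc",
    "ensemble_stats",
    "parameter_sweep",
    "CORE_THRESHOLD",
    "BOUNDARY_THRESHOLD",
    "SPHERE_THRESHOLD",
]

#: classifier thresholds on region-local packing densities
CORE_THRESHOLD = 0.20
BOUNDARY_THRESHOLD = 0.18
SPHERE_THRESHOLD = 0.18


# ---------------------------------------------------------------------------
# voxel field
# ---------------------------------------------------------------------------


@dataclass
class VoxelField:
    """Scalar field on a uniform voxelization of a bounding cube.

    ``values`` has shape (N_V, N_V, N_V); binary {0,1} for a single coil,
    real-valued in [0,1] for ensemble means.
    """

    origin: np.ndarray
    edge_length: float
    n_voxels: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_voxels,) * 3:
            raise ValueError("values must be (N_V, N_V, N_V)")

    @property
    def voxel_size(self) -> float:
        return self.edge_length / self.n_voxels

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def centers(self) -> np.ndarray:
        """(N_V^3, 3) voxel center coordinates, k fastest (C order)."""
        h = self.voxel_size
        idx = np.arange(self.n_voxels)
        ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
        ctr = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.origin + (ctr + 0.5) * h

    def volume(self) -> float:
        """Represented volume: sum of values times the voxel volume."""
        return float(self.values.sum() * self.voxel_volume)

    def same_grid(self, other: "VoxelField") -> bool:
        return (
            self.n_voxels == other.n_voxels
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.edge_length, other.edge_length)
        )


def bounding_cube(mesh: trimesh.Trimesh, margin: float = 0.0) -> tuple[np.ndarray, float]:
    """Axis-aligned bounding cube (origin, edge length) of a surface."""
    lo, hi = mesh.bounds
    a = float((hi - lo).max()) + 2 * margin
    center = 0.5 * (lo + hi)
    return center - a / 2.0, a


# ---------------------------------------------------------------------------
# signed distance
# ---------------------------------------------------------------------------


def mesh_sdf(surface: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Signed distance to a closed surface: negative inside, positive
    outside, zero on the surface.

    The magnitude is the exact distance to the nearest triangle (KD-tree
    broad phase over triangle centers, then exact point-triangle
    distances); the sign comes from the parity of surface crossings along
    a vertical ray, which is robust on watertight meshes regardless of
    local concavity.
    """
    points = np.asarray(points, dtype=float)
    single = points.ndim == 1
    pts = points.reshape(-1, 3)
    dist = _unsigned_mesh_distance(surface, pts)
    inside = _contains_z_parity(surface, pts)
    sd = np.where(inside, -dist, dist)
    return float(sd[0]) if single else sd


def _bvh_build(tri: np.ndarray):
    """Median-split BVH over triangles; flat arrays for the jit kernel."""
    n = len(tri)
    lo_t = tri.min(axis=1)
    hi_t = tri.max(axis=1)
    cen = tri.mean(axis=1)
    node_lo = []
    node_hi = []
    node_left = []
    node_right = []
    node_start = []
    node_count = []
    order: list[int] = []

    def build(ids: np.ndarray) -> int:
        idx = len(node_lo)
        node_lo.append(lo_t[ids].min(axis=0))
        node_hi.append(hi_t[ids].max(axis=0))
        node_left.append(-1)
        node_right.append(-1)
        if len(ids) <= 4:
            node_start.append(len(order))
            node_count.append(len(ids))
            order.extend(ids.tolist())
            return idx
        node_start.append(-1)
        node_count.append(0)
        span = node_hi[idx] - node_lo[idx]
        ax = int(np.argmax(span))
        half = len(ids) // 2
        part = ids[np.argsort(cen[ids, ax], kind="stable")]
        node_left[idx] = build(part[:half])
        node_right[idx] = build(part[half:])
        return idx

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        build(np.arange(n))
    finally:
        sys.setrecursionlimit(old)
    return (
        np.asarray(node_lo),
        np.asarray(node_hi),
        np.asarray(node_left, dtype=np.int64),
        np.asarray(node_right, dtype=np.int64),
        np.asarray(node_start, dtype=np.int64),
        np.asarray(node_count, dtype=np.int64),
        np.asarray(order, dtype=np.int64),
    )


def _bvh_distance_kernel(pts, tri, node_lo, node_hi, left, right, start, count, order, out):
    """Branch-and-bound nearest-triangle distance per query point."""
    stack = np.empty(128, dtype=np.int64)
    for q in range(len(pts)):
        px, py, pz = pts[q, 0], pts[q, 1], pts[q, 2]
        best = 1.0e300
        top = 0
        stack[0] = 0
        while top >= 0:
            node = stack[top]
            top -= 1
            # squared distance to node AABB
            dx = max(node_lo[node, 0] - px, 0.0, px - node_hi[node, 0])
            dy = max(node_lo[node, 1] - py, 0.0, py - node_hi[node, 1])
            dz = max(node_lo[node, 2] - pz, 0.0, pz - node_hi[node, 2])
            if dx * dx + dy * dy + dz * dz >= best:
                continue
            if count[node] > 0:
                for s in range(start[node], start[node] + count[node]):
                    t = order[s]
                    d2 = _point_tri_dist2(
                        px, py, pz,
                        tri[t, 0, 0], tri[t, 0, 1], tri[t, 0, 2],
                        tri[t, 1, 0], tri[t, 1, 1], tri[t, 1, 2],
                        tri[t, 2, 0], tri[t, 2, 1], tri[t, 2, 2],
                    )
                    if d2 < best:
                        best = d2
            else:
                top += 1
                stack[top] = left[node]
                top += 1
                stack[top] = right[node]
        out[q] = best**0.5


def _point_tri_dist2(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Squared point-triangle distance (Ericson closest-feature walk)."""
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return apx * apx + apy * apy + apz * apz
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bpx * bpx + bpy * bpy + bpz * bpz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        qx, qy, qz = ax + v * abx - px, ay + v * aby - py, az + v * abz - pz
        return qx * qx + qy * qy + qz * qz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cpx * cpx + cpy * cpy + cpz * cpz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        qx, qy, qz = ax + w * acx - px, ay + w * acy - py, az + w * acz - pz
        return qx * qx + qy * qy + qz * qz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        qx = bx + w * (cx - bx) - px
        qy = by + w * (cy - by) - py
        qz = bz + w * (cz - bz) - pz
        return qx * qx + qy * qy + qz * qz
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    qx = ax + v * abx + w * acx - px
    qy = ay + v * aby + w * acy - py
    qz = az + v * abz + w * acz - pz
    return qx * qx + qy * qy + qz * qz


try:  # jit the BVH traversal; pure Python fallback works but is slow
    from numba import njit as _njit_occ

    _point_tri_dist2 = _njit_occ(cache=True, inline="always")(_point_tri_dist2)
    _bvh_distance_kernel = _njit_occ(cache=True)(_bvh_distance_kernel)
except ImportError:  # pragma: no cover
    pass


def _unsigned_mesh_distance(surface: trimesh.Trimesh, pts: np.ndarray) -> np.ndarray:
    tri = np.ascontiguousarray(surface.vertices[surface.faces], dtype=float)
    bvh = _bvh_build(tri)
    out = np.empty(len(pts))
    _bvh_distance_kernel(np.ascontiguousarray(pts, dtype=float), tri, *bvh, out)
    return out


def _contains_z_parity(surface: trimesh.Trimesh, pts: np.ndarray) -> np.ndarray:
    """Inside test: odd number of triangle crossings above each point
    along +z.  Queries are nudged by a tiny xy offset so rays through
    shared triangle edges (measure zero) are not double counted."""
    tri = surface.vertices[surface.faces]
    eps = 1e-7 * max(float(surface.scale), 1.0)
    qx = pts[:, 0] + eps * 0.5
    qy = pts[:, 1] + eps
    order_x = np.argsort(qx)
    sx = qx[order_x]
    count = np.zeros(len(pts), dtype=np.int64)
    ax, ay, az = tri[:, 0, 0], tri[:, 0, 1], tri[:, 0, 2]
    bx, by, bz = tri[:, 1, 0], tri[:, 1, 1], tri[:, 1, 2]
    cx, cy, cz = tri[:, 2, 0], tri[:, 2, 1], tri[:, 2, 2]
    xmin = np.minimum(np.minimum(ax, bx), cx)
    xmax = np.maximum(np.maximum(ax, bx), cx)
    ymin = np.minimum(np.minimum(ay, by), cy)
    ymax = np.maximum(np.maximum(ay, by), cy)
    for t in range(len(tri)):
        lo = np.searchsorted(sx, xmin[t])
        hi = np.searchsorted(sx, xmax[t], side="right")
        if hi <= lo:
            continue
        cand = order_x[lo:hi]
        cand = cand[(qy[cand] >= ymin[t]) & (qy[cand] <= ymax[t])]
        if len(cand) == 0:
            continue
        px, py = qx[cand], qy[cand]
        d1 = (bx[t] - ax[t]) * (py - ay[t]) - (by[t] - ay[t]) * (px - ax[t])
        d2 = (cx[t] - bx[t]) * (py - by[t]) - (cy[t] - by[t]) * (px - bx[t])
        d3 = (ax[t] - cx[t]) * (py - cy[t]) - (ay[t] - cy[t]) * (px - cx[t])
        inside2d = ((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | ((d1 <= 0) & (d2 <= 0) & (d3 <= 0))
        if not np.any(inside2d):
            continue
        cand = cand[inside2d]
        px, py = qx[cand], qy[cand]
        # plane z at (px, py)
        u = np.array([bx[t] - ax[t], by[t] - ay[t], bz[t] - az[t]])
        v = np.array([cx[t] - ax[t], cy[t] - ay[t], cz[t] - az[t]])
        nrm = np.cross(u, v)
        if abs(nrm[2]) < 1e-14:
            continue
        z = az[t] - (nrm[0] * (px - ax[t]) + nrm[1] * (py - ay[t])) / nrm[2]
        count[cand] += (z > pts[cand, 2]).astype(np.int64)
    return (count % 2) == 1


# ---------------------------------------------------------------------------
# coil voxelization
# ---------------------------------------------------------------------------


def voxelize_coil(
    centerline: np.ndarray,
    D2: float,
    origin: np.ndarray,
    edge_length: float,
    n_voxels: int = 70,
) -> VoxelField:
    """Binary voxelization of the swept coil volume.

    A voxel is set when its center lies within ``D2/2`` of the centerline
    polyline (union of segment capsules).  An empty centerline yields an
    all-zero field.  Parts of the coil that left the cube (for example a
    loop hanging into the parent vessel below the aneurysm's bounding
    cube) simply mark no voxels; a polyline lying entirely outside the
    cube raises an error.
    """
    origin = np.asarray(origin, dtype=float)
    values = np.zeros((n_voxels,) * 3)
    centerline = np.asarray(centerline, dtype=float).reshape(-1, 3)
    fld = VoxelField(origin, float(edge_length), int(n_voxels), values)
    if len(centerline) == 0:
        return fld
    inside = np.all(
        (centerline >= origin - 1e-9)
        & (centerline <= origin + edge_length + 1e-9),
        axis=1,
    )
    if not inside.any():
        raise ValueError("coil centerline lies entirely outside the bounding cube")
    h = fld.voxel_size
    r = D2 / 2.0
    if len(centerline) == 1:
        segs_p = centerline
        segs_d = np.zeros((1, 3))
    else:
        segs_p = centerline[:-1]
        segs_d = centerline[1:] - centerline[:-1]
    for p, d in zip(segs_p, segs_d):
        lo = np.minimum(p, p + d) - r
        hi = np.maximum(p, p + d) + r
        i0 = np.maximum(np.floor((lo - origin) / h - 0.5).astype(int), 0)
        i1 = np.minimum(np.ceil((hi - origin) / h + 0.5).astype(int), n_voxels - 1)
        if np.any(i0 > i1):
            continue
        ax = [np.arange(i0[k], i1[k] + 1) for k in range(3)]
        ii, jj, kk = np.meshgrid(*ax, indexing="ij")
        ctr = origin + (np.stack([ii, jj, kk], axis=-1) + 0.5) * h
        rel = ctr - p
        dd = float(np.dot(d, d))
        if dd > 0:
            tpar = np.clip(np.einsum("...k,k->...", rel, d) / dd, 0.0, 1.0)
            closest = p + tpar[..., None] * d
        else:
            closest = np.broadcast_to(p, ctr.shape)
        dist2 = np.sum((ctr - closest) ** 2, axis=-1)
        hit = dist2 <= r * r
        values[ii[hit], jj[hit], kk[hit]] = 1.0
    return fld


# ---------------------------------------------------------------------------
# region partition
# ---------------------------------------------------------------------------


@dataclass
class RegionPartition:
    """Equal-volume core/boundary split of the aneurysm interior plus the
    neck sphere, on a fixed voxel grid."""

    core_mask: np.ndarray
    boundary_mask: np.ndarray
    interior_mask: np.ndarray
    sphere_mask: np.ndarray
    iso_value: float
    sphere_center: np.ndarray
    sphere_radius: float
    voxel_volume: float

    @property
    def V_C(self) -> float:
        return float(self.core_mask.sum() * self.voxel_volume)

    @property
    def V_B(self) -> float:
        return float(self.boundary_mask.sum() * self.voxel_volume)

    @property
    def V_A(self) -> float:
        return float(self.interior_mask.sum() * self.voxel_volume)

    @property
    def V_S(self) -> float:
        """Sphere volume restricted to the aneurysm interior."""
        return float(self.sphere_mask.sum() * self.voxel_volume)


def partition_regions(
    domain: AneurysmDomain,
    grid: VoxelField | None = None,
    n_voxels: int = 70,
    sphere_center: np.ndarray | None = None,
    sphere_radius: float | None = None,
    sdf_values: np.ndarray | None = None,
) -> RegionPartition:
    """Partition the aneurysm interior into equal-volume core and
    boundary regions by bisecting on the SDF level set.

    The core is the deep-interior set ``sdf <= c``; the iso-value ``c`` is
    found by bisection until the core holds half the interior voxel
    volume.  The default neck sphere sits at the neck-opening centroid
    with the neck radius.  ``grid`` fixes the voxel layout (so coil
    fields and partitions align); by default the dome's bounding cube at
    ``n_voxels`` per axis is used.
    """
    if grid is None:
        origin, a = bounding_cube(domain.dome_mesh)
        grid = VoxelField(origin, a, n_voxels, np.zeros((n_voxels,) * 3))
    pts = grid.centers()
    if sdf_values is None:
        sdf_values = mesh_sdf(domain.dome_mesh, pts)
    sdf = np.asarray(sdf_values, dtype=float).reshape(grid.values.shape)
    interior = sdf < 0.0
    n_int = int(interior.sum())
    if n_int == 0:
        raise ValueError("no voxel centers inside the aneurysm; grid too coarse")
    target = n_int / 2.0
    lo = float(sdf[interior].min())
    hi = 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if (sdf[interior] <= mid).sum() < target:
            lo = mid
        else:
            hi = mid
    iso = 0.5 * (lo + hi)
    core = interior & (sdf <= iso)
    boundary = interior & ~core

    if sphere_center is None or sphere_radius is None:
        c_def, r_def = domain.neck_sphere()
        sphere_center = c_def if sphere_center is None else np.asarray(sphere_center, float)
        sphere_radius = r_def if sphere_radius is None else float(sphere_radius)
    d2 = np.sum((pts - sphere_center) ** 2, axis=1).reshape(grid.values.shape)
    sphere = interior & (d2 <= sphere_radius**2)

    return RegionPartition(
        core_mask=core,
        boundary_mask=boundary,
        interior_mask=interior,
        sphere_mask=sphere,
        iso_value=iso,
        sphere_center=np.asarray(sphere_center, dtype=float),
        sphere_radius=float(sphere_radius),
        voxel_volume=grid.voxel_volume,
    )


# ---------------------------------------------------------------------------
# fractions and classification
# ---------------------------------------------------------------------------


@dataclass
class OcclusionReport:
    """Volume fractions, region-local packing densities and class label."""

    psi_BA: float
    psi_CA: float
    psi_AA: float
    psi_SS: float
    pd_core: float
    pd_boundary: float
    pd_sphere: float
    label: str
    psi_sigma: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "psi_BA": self.psi_BA,
            "psi_CA": self.psi_CA,
            "psi_AA": self.psi_AA,
            "psi_SS": self.psi_SS,
            "pd_core": self.pd_core,
            "pd_boundary": self.pd_boundary,
            "pd_sphere": self.pd_sphere,
            "label": self.label,
            "psi_sigma": self.psi_sigma,
            "metadata": self.metadata,
        }


def volume_fractions(field_: VoxelField, partition: RegionPartition) -> dict:
    """Region-integrated coil volume over the reference volumes.

    ``psi_BA``, ``psi_CA`` and ``psi_AA`` are referenced to the full
    aneurysm volume (so ``psi_BA + psi_CA = psi_AA``); ``psi_SS`` is
    referenced to the sphere-within-aneurysm volume.  Region-local
    packing densities (coil volume over region volume) are included for
    the classifier.
    """
    vv = partition.voxel_volume
    vals = field_.values
    vol_b = float(vals[partition.boundary_mask].sum() * vv)
    vol_c = float(vals[partition.core_mask].sum() * vv)
    vol_a = float(vals[partition.interior_mask].sum() * vv)
    vol_s = float(vals[partition.sphere_mask].sum() * vv)
    V_A = partition.V_A
    return {
        "psi_BA": vol_b / V_A,
        "psi_CA": vol_c / V_A,
        "psi_AA": vol_a / V_A,
        "psi_SS": vol_s / partition.V_S if partition.V_S > 0 else 0.0,
        "pd_core": vol_c / partition.V_C if partition.V_C > 0 else 0.0,
        "pd_boundary": vol_b / partition.V_B if partition.V_B > 0 else 0.0,
        "pd_sphere": vol_s / partition.V_S if partition.V_S > 0 else 0.0,
    }


def classify_rroc(
    pd_core: float,
    pd_boundary: float,
    pd_sphere: float,
    core_threshold: float = CORE_THRESHOLD,
    boundary_threshold: float = BOUNDARY_THRESHOLD,
    sphere_threshold: float = SPHERE_THRESHOLD,
) -> str:
    """Raymond-Roy-type class from region-local packing densities.

    Thresholds are inclusive ("reaches ... and above").  Truth table:
    full core + full boundary -> I (sphere full) or II (sphere empty);
    empty core + full boundary -> IIIa; full core + empty boundary ->
    IIIb; both empty -> Fail (coil migrated into the parent vessel).
    """
    core_full = pd_core >= core_threshold
    boundary_full = pd_boundary >= boundary_threshold
    sphere_full = pd_sphere >= sphere_threshold
    if boundary_full:
        if core_full:
            return "I" if sphere_full else "II"
        return "IIIa"
    if core_full:
        return "IIIb"
    return "Fail"


def make_report(
    field_: VoxelField,
    partition: RegionPartition,
    metadata: dict | None = None,
) -> OcclusionReport:
    """Volume fractions + classification for one (or one mean) field."""
    fr = volume_fractions(field_, partition)
    label = classify_rroc(fr["pd_core"], fr["pd_boundary"], fr["pd_sphere"])
    meta = {
        "sphere_center": [float(x) for x in partition.sphere_center],
        "sphere_radius": partition.sphere_radius,
        "iso_value": partition.iso_value,
        "V_A": partition.V_A,
        "V_C": partition.V_C,
        "V_B": partition.V_B,
        "V_S": partition.V_S,
    }
    if metadata:
        meta.update(metadata)
    return OcclusionReport(
        psi_BA=fr["psi_BA"],
        psi_CA=fr["psi_CA"],
        psi_AA=fr["psi_AA"],
        psi_SS=fr["psi_SS"],
        pd_core=fr["pd_core"],
        pd_boundary=fr["pd_boundary"],
        pd_sphere=fr["pd_sphere"],
        label=label,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------


def ensemble_stats(
    fields: list[VoxelField],
    partition: RegionPartition | None = None,
) -> dict:
    """Pointwise empirical mean/variance of voxelized coil distributions
    and, with a partition, region-integrated means and deviations.

    All fields must share the grid.  The population (1/N) convention is
    used throughout.  The region deviation is
    ``sigma_V^2 = 1/N sum_i (int_V (psi_bar - psi_i))^2``.
    """
    if not fields:
        raise ValueError("need at least one field")
    base = fields[0]
    for f in fields[1:]:
        if not base.same_grid(f):
            raise ValueError("ensemble fields must share the voxel grid")
    stack = np.stack([f.values for f in fields])
    mean = stack.mean(axis=0)
    var = stack.var(axis=0)
    out = {
        "mean_field": VoxelField(base.origin, base.edge_length, base.n_voxels, mean),
        "var_field": VoxelField(base.origin, base.edge_length, base.n_voxels, var),
        "n": len(fields),
    }
    if partition is not None:
        vv = partition.voxel_volume
        regions = {
            "BA": partition.boundary_mask,
            "CA": partition.core_mask,
            "AA": partition.interior_mask,
            "SS": partition.sphere_mask,
        }
        psi_v = {}
        psi_sigma = {}
        for name, mask in regions.items():
            ints = stack[:, mask].sum(axis=1) * vv
            psi_v[name] = float(ints.mean())
            psi_sigma[name] = float(np.sqrt(np.mean((ints.mean() - ints) ** 2)))
        out["psi_V"] = psi_v
        out["psi_sigma_V"] = psi_sigma
    return out


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    variable: str
    samples: np.ndarray
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    bin_counts: np.ndarray
    fractions: dict
    ci_half_width: dict
    underfilled_bins: np.ndarray


def parameter_sweep(
    simulate,
    variable: str,
    interval: tuple[float, float],
    n_samples: int,
    partition: RegionPartition,
    n_bins: int = 5,
    min_per_bin: int = 30,
    seed: int = 0,
) -> SweepResult:
    """Uniform-sampling sensitivity sweep of a coil parameter.

    ``simulate(value, sample_seed)`` must return the voxelized deployment
    for parameter value ``value``.  The interval is partitioned into
    ``n_bins`` equal subintervals; per bin the ensemble volume fractions
    (with their normal-approximation 95% confidence half-widths) are
    computed.  Bins holding fewer than ``min_per_bin`` samples are
    flagged with a warning.
    """
    rng = np.random.default_rng(seed)
    lo, hi = float(interval[0]), float(interval[1])
    samples = rng.uniform(lo, hi, int(n_samples))
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fracs = {k: np.full(n_bins, np.nan) for k in ("BA", "CA", "AA", "SS")}
    ci = {k: np.full(n_bins, np.nan) for k in ("BA", "CA", "AA", "SS")}
    counts = np.zeros(n_bins, dtype=int)
    under = np.zeros(n_bins, dtype=bool)
    if n_samples == 0:
        return SweepResult(variable, samples, edges, centers, counts, fracs, ci, under)

    fields = [simulate(float(z), int(rng.integers(0, 2**31 - 1))) for z in samples]
    which = np.clip(np.searchsorted(edges, samples, side="right") - 1, 0, n_bins - 1)
    V_A = partition.V_A
    V_S = partition.V_S
    ref = {"BA": V_A, "CA": V_A, "AA": V_A, "SS": V_S}
    for b in range(n_bins):
        members = [fields[i] for i in np.flatnonzero(which == b)]
        counts[b] = len(members)
        if counts[b] == 0:
            under[b] = True
            continue
        if counts[b] < min_per_bin:
            under[b] = True
            warnings.warn(
                f"sweep bin {b} for {variable} holds {counts[b]} < {min_per_bin} samples"
            )
        stats = ensemble_stats(members, partition)
        for k in fracs:
            fracs[k][b] = stats["psi_V"][k] / ref[k]
            ci[k][b] = 1.96 * stats["psi_sigma_V"][k] / ref[k] / np.sqrt(counts[b])
    return SweepResult(variable, samples, edges, centers, counts, fracs, ci, under)
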