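"""Aneurysm/vessel geometry, micro-catheter spline and coil shape programs.

The simulator runs in two phases: coils are first deployed into the
neck-cut aneurysm sack (a closed "dome" mesh), then the dome is swapped
for the full vessel geometry for a final settling fraction of the run.
For self-contained studies a synthetic dome (spherical sack with a
circular neck and a short parent-lumen stem) replaces patient meshes;
user-supplied STL/OBJ/PLY meshes are accepted through the same interface.

All meshes are triangulated surfaces in a shared Cartesian mm frame with
outward-oriented normals (counterclockwise winding seen from outside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from aneucoil.rod import CoilSpec, NaturalShape

__all__ = [
    "AneurysmDomain",
    "CatheterSpline",
    "ShapeProgram",
    "load_mesh",
    "save_mesh",
    "mesh_volume",
    "make_synthetic_aneurysm",
    "cut_at_neck",
    "natural_shape",
    "perturb_catheter_tip",
]


# ---------------------------------------------------------------------------
# mesh I/O and validation
# ---------------------------------------------------------------------------


def load_mesh(path: str | Path, strict: bool = True) -> trimesh.Trimesh:
    """Load an STL/OBJ/PLY surface and validate it.

    With ``strict`` the mesh must be watertight with consistently wound,
    outward-oriented faces (positive enclosed volume); otherwise problems
    only produce a warning from trimesh's processing.
    """
    mesh = trimesh.load_mesh(str(path), process=True)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a single triangulated surface")
    if strict:
        validate_mesh(mesh, str(path))
    return mesh


def validate_mesh(mesh: trimesh.Trimesh, label: str = "mesh") -> None:
    if not mesh.is_watertight:
        raise ValueError(f"{label}: surface is not watertight")
    if not mesh.is_winding_consistent:
        raise ValueError(f"{label}: inconsistent triangle winding")
    if mesh.volume <= 0:
        raise ValueError(f"{label}: normals are inverted (negative enclosed volume)")


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Signed enclosed volume by the divergence theorem (mm^3)."""
    return float(mesh.volume)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AneurysmDomain:
    """Two-phase wall geometry plus neck metadata.

    ``dome_mesh`` is the closed neck-cut sack used while the coil is being
    inserted; ``vessel_mesh`` is the full geometry enabled for the final
    settling phase.  The neck plane (point + unit normal, normal pointing
    into the dome) and the largest inscribed neck-opening radius drive the
    default neck-sphere of the occlusion classifier.
    """

    dome_mesh: trimesh.Trimesh
    vessel_mesh: trimesh.Trimesh
    neck_plane_point: np.ndarray
    neck_plane_normal: np.ndarray
    neck_radius: float
    neck_centroid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.neck_plane_point = np.asarray(self.neck_plane_point, dtype=float)
        n = np.asarray(self.neck_plane_normal, dtype=float)
        self.neck_plane_normal = n / np.linalg.norm(n)
        if self.neck_centroid is None:
            self.neck_centroid = self.neck_plane_point
        validate_mesh(self.dome_mesh, "dome mesh")
        validate_mesh(self.vessel_mesh, "vessel mesh")

    @property
    def V_A(self) -> float:
        """Aneurysm (dome) volume in mm^3."""
        return mesh_volume(self.dome_mesh)

    def neck_sphere(self) -> tuple[np.ndarray, float]:
        """Default neck sphere: centered at the opening centroid on the
        neck plane with radius equal to the neck-opening radius."""
        return np.asarray(self.neck_centroid, dtype=float), float(self.neck_radius)


@dataclass
class CatheterSpline:
    """Micro-catheter centerline: quadratic Bezier through 3 control
    points, swept into a rigid lidless tube of ``tube_radius``."""

    control_points: np.ndarray
    tube_radius: float = 0.25
    n_samples: int = 400

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.shape != (3, 3):
            raise ValueError("catheter spline needs exactly 3 control points")
        u = np.linspace(0.0, 1.0, self.n_samples)
        pts = self._bezier(u)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])
        self._samples = pts
        if self.length <= 0:
            raise ValueError("catheter spline has zero length")

    def _bezier(self, u: np.ndarray) -> np.ndarray:
        p0, p1, p2 = self.control_points
        u = np.asarray(u, dtype=float)[:, None]
        return (1 - u) ** 2 * p0 + 2 * u * (1 - u) * p1 + u**2 * p2

    @property
    def length(self) -> float:
        return float(self._arc[-1])

    def point_at(self, s: np.ndarray) -> np.ndarray:
        """Position at arc length ``s``; values outside [0, L] continue
        straight along the end tangents (the coil reservoir behind the
        inlet and any overshoot at the tip)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((len(s), 3))
        inside = (s >= 0) & (s <= self.length)
        if np.any(inside):
            for k in range(3):
                out[inside, k] = np.interp(s[inside], self._arc, self._samples[:, k])
        t0 = self.tangent_at(np.array([0.0]))[0]
        t1 = self.tangent_at(np.array([self.length]))[0]
        below = s < 0
        above = s > self.length
        out[below] = self._samples[0] + s[below, None] * t0
        out[above] = self._samples[-1] + (s[above] - self.length)[:, None] * t1
        return out

    def tangent_at(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        u = np.clip(s / self.length, 0.0, 1.0)
        p0, p1, p2 = self.control_points
        d = 2 * (1 - u)[:, None] * (p1 - p0) + 2 * u[:, None] * (p2 - p1)
        n = np.linalg.norm(d, axis=1)
        n[n == 0] = 1.0
        return d / n[:, None]

    @property
    def tip_point(self) -> np.ndarray:
        return self._samples[-1].copy()

    @property
    def tip_tangent(self) -> np.ndarray:
        return self.tangent_at(np.array([self.length]))[0]

    def tube_mesh(self, n_circ: int = 16, n_axial: int = 40) -> trimesh.Trimesh:
        """Open cylindrical tube surface along the spline (no lids).

        Normals point outward from the tube axis.
        """
        s = np.linspace(0.0, self.length, n_axial)
        pts = self.point_at(s)
        tans = self.tangent_at(s)
        # transport a frame along the spline
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, tans[0])) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        verts = []
        u = ref - np.dot(ref, tans[0]) * tans[0]
        u /= np.linalg.norm(u)
        for i in range(n_axial):
            t = tans[i]
            u = u - np.dot(u, t) * t
            u /= np.linalg.norm(u)
            v = np.cross(t, u)
            ang = 2 * np.pi * np.arange(n_circ) / n_circ
            ring = pts[i] + self.tube_radius * (
                np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
            )
            verts.append(ring)
        verts = np.concatenate(verts, axis=0)
        faces = []
        for i in range(n_axial - 1):
            for j in range(n_circ):
                a = i * n_circ + j
                b = i * n_circ + (j + 1) % n_circ
                c = (i + 1) * n_circ + j
                d = (i + 1) * n_circ + (j + 1) % n_circ
                faces.append([a, b, d])
                faces.append([a, d, c])
        mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
        # orient normals outward from the local axis
        centers = mesh.triangles_center
        seg_idx = np.clip(
            np.searchsorted(s, np.einsum("ij,j->i", centers - pts[0], tans[0])), 0, n_axial - 1
        )
        radial = centers - pts[seg_idx]
        flip = np.einsum("ij,ij->i", mesh.face_normals, radial) < 0
        faces = mesh.faces.copy()
        faces[flip] = faces[flip][:, ::-1]
        return trimesh.Trimesh(vertices=mesh.vertices, faces=faces, process=False)


@dataclass
class ShapeProgram:
    """Recipe for a coil's imprinted natural shape.

    ``kind``: ``straight`` (zero curvature), ``helix`` (constant-radius
    helix of imprint diameter D3 with loop spacing ``loop_spacing``,
    default 1.2 D2) or ``complex3d`` (loops of varying orientation on a
    sphere of diameter D3, a frozen parametric reference shape).
    """

    kind: str = "helix"
    loop_spacing: float | None = None
    n_nodes: int = 300

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "helix", "complex3d"):
            raise ValueError(f"unknown shape program {self.kind!r}")


# ---------------------------------------------------------------------------
# synthetic geometry
# ---------------------------------------------------------------------------


def _revolve(profile_rz: np.ndarray, n_theta: int) -> trimesh.Trimesh:
    """Revolve an (r, z) profile around the z axis into a closed surface.

    The profile runs from the top pole (r=0) down; the last point is a
    bottom pole (r=0).  Interior points must have r > 0.
    """
    r = profile_rz[:, 0]
    z = profile_rz[:, 1]
    ang = 2 * np.pi * np.arange(n_theta) / n_theta
    verts = [np.array([[0.0, 0.0, z[0]]])]
    ring_start = []
    for i in range(1, len(r) - 1):
        ring_start.append(len(np.concatenate(verts)) if verts else 0)
        ring = np.column_stack(
            [r[i] * np.cos(ang), r[i] * np.sin(ang), np.full(n_theta, z[i])]
        )
        verts.append(ring)
    verts.append(np.array([[0.0, 0.0, z[-1]]]))
    V = np.concatenate(verts, axis=0)
    top = 0
    bottom = len(V) - 1
    n_rings = len(r) - 2
    faces = []
    for j in range(n_theta):
        a = 1 + j
        b = 1 + (j + 1) % n_theta
        faces.append([top, b, a])
    for i in range(n_rings - 1):
        base = 1 + i * n_theta
        nxt = base + n_theta
        for j in range(n_theta):
            a = base + j
            b = base + (j + 1) % n_theta
            c = nxt + j
            d = nxt + (j + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    base = 1 + (n_rings - 1) * n_theta
    for j in range(n_theta):
        a = base + j
        b = base + (j + 1) % n_theta
        faces.append([a, b, bottom])
    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def make_synthetic_aneurysm(
    dome_radius: float = 2.5,
    neck_radius: float = 1.0,
    parent_radius: float = 1.5,
    resolution: int = 28,
    seed: int | None = None,
    bump_amplitude: float = 0.0,
    n_bumps: int = 3,
) -> AneurysmDomain:
    """Synthetic saccular aneurysm: a spherical dome with a circular neck.

    The dome mesh is the sphere cap above the neck plane, closed by a flat
    neck cap (phase-1 geometry).  The vessel mesh extends the sack with a
    cylindrical stem of depth ``2 * parent_radius`` below the neck,
    standing in for the parent-lumen space a migrating coil could enter.
    Defaults (2.5 mm dome radius, 1 mm neck) sit in the "very small"
    clinical size class (dome 2-7 mm).  ``bump_amplitude`` adds smooth
    seeded radial perturbations for ensemble variety.
    """
    if not 0 < neck_radius < dome_radius:
        raise ValueError("need 0 < neck_radius < dome_radius")
    R = float(dome_radius)
    h = float(np.sqrt(R**2 - neck_radius**2))  # neck plane at z = -h
    # dome profile: from top pole down to the neck circle
    theta_max = np.pi - np.arcsin(neck_radius / R)
    n_prof = max(resolution, 12)
    theta = np.linspace(0.0, theta_max, n_prof)
    r_prof = R * np.sin(theta)
    z_prof = R * np.cos(theta)
    if bump_amplitude > 0.0:
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 2 * np.pi, n_bumps)
        amp = rng.uniform(0.3, 1.0, n_bumps) * bump_amplitude
        scale = np.ones_like(theta)
        for k in range(n_bumps):
            scale += amp[k] * np.sin((k + 2) * theta + phase[k]) * np.sin(theta) ** 2
        r_prof = r_prof * scale
        z_prof = z_prof * np.where(np.sin(theta) > 0, 1.0, 1.0)
    # close the dome with a flat cap across the neck opening
    cap_r = np.linspace(r_prof[-1], 0.0, max(4, resolution // 4))[1:]
    prof_dome = np.column_stack(
        [
            np.concatenate([r_prof, cap_r]),
            np.concatenate([z_prof, np.full(len(cap_r), -h)]),
        ]
    )
    dome = _revolve(prof_dome, n_theta=resolution)

    # full vessel: dome + cylindrical stem below the neck, capped at the bottom
    stem_depth = 2.0 * parent_radius
    stem_z = np.linspace(-h, -h - stem_depth, max(6, resolution // 3))[1:]
    stem_r = np.full(len(stem_z), neck_radius)
    cap2 = np.linspace(neck_radius, 0.0, max(4, resolution // 4))[1:]
    prof_full = np.column_stack(
        [
            np.concatenate([r_prof, stem_r, cap2]),
            np.concatenate([z_prof, stem_z, np.full(len(cap2), -h - stem_depth)]),
        ]
    )
    vessel = _revolve(prof_full, n_theta=resolution)

    return AneurysmDomain(
        dome_mesh=dome,
        vessel_mesh=vessel,
        neck_plane_point=np.array([0.0, 0.0, -h]),
        neck_plane_normal=np.array([0.0, 0.0, 1.0]),
        neck_radius=float(neck_radius),
        neck_centroid=np.array([0.0, 0.0, -h]),
    )


def cut_at_neck(
    vessel_mesh: trimesh.Trimesh,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
) -> trimesh.Trimesh:
    """Cut the aneurysm sack off the parent vessel at the neck plane.

    Keeps the side the (unit) normal points into and caps the cut,
    producing a watertight dome mesh for the insertion phase.
    """
    plane_point = np.asarray(plane_point, dtype=float)
    plane_normal = np.asarray(plane_normal, dtype=float)
    plane_normal = plane_normal / np.linalg.norm(plane_normal)
    sdist = np.einsum("ij,j->i", vessel_mesh.vertices - plane_point, plane_normal)
    if np.all(sdist > 0) or np.all(sdist < 0):
        raise ValueError("neck plane does not intersect the vessel mesh")
    open_dome = trimesh.intersections.slice_mesh_plane(
        vessel_mesh, plane_normal, plane_point, cap=False
    )
    # weld the duplicated vertices the slicer introduces along the cut
    open_dome.merge_vertices(digits_vertex=7)
    dome = _cap_boundary_loops(open_dome)
    dome.process()
    validate_mesh(dome, "neck-cut dome")
    return dome


def _cap_boundary_loops(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Close planar holes by fanning each boundary loop from its centroid.

    Winding of the cap triangles is induced by the open boundary edges,
    so the result is consistently oriented.  Loops are assumed star-shaped
    with respect to their centroid (true for neck cross sections).
    """
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_sorted = {tuple(e) for e in unique[counts == 1]}
    if not boundary_sorted:
        return mesh
    # recover directed boundary edges as they appear in faces
    directed = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if tuple(sorted((a, b))) in boundary_sorted:
                directed[a] = b
    verts = [mesh.vertices]
    faces = [mesh.faces]
    n_v = len(mesh.vertices)
    remaining = dict(directed)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        while True:
            nxt = remaining.pop(loop[-1])
            if nxt == start:
                break
            loop.append(nxt)
        loop = np.asarray(loop)
        centroid = mesh.vertices[loop].mean(axis=0)
        verts.append(centroid[None, :])
        cap = np.column_stack(
            [np.full(len(loop), n_v), np.roll(loop, -1), loop]
        )
        faces.append(cap)
        n_v += 1
    return trimesh.Trimesh(
        vertices=np.concatenate(verts, axis=0),
        faces=np.concatenate(faces, axis=0),
        process=False,
    )


# ---------------------------------------------------------------------------
# natural shapes
# ---------------------------------------------------------------------------


def _resample_constant_chord(dense: np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a dense polyline to ``n_nodes`` points with constant chord
    length: Newton marching along the arclength parametrization (the
    chord grows with unit slope in arclength to leading order), with a
    secant iteration on the common chord so the march ends exactly at
    the curve end."""
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]

    def point(s: float) -> np.ndarray:
        return np.array([np.interp(s, arc, dense[:, k]) for k in range(3)])

    def march(chord: float) -> tuple[np.ndarray, float]:
        pts = [dense[0]]
        s = 0.0
        for _ in range(n_nodes - 1):
            t = min(s + chord, total)
            for _ in range(40):
                p = point(t)
                err = np.linalg.norm(p - pts[-1]) - chord
                if abs(err) < 1e-13 * chord:
                    break
                t = min(max(t - err, s), total + 0.5 * chord)
            pts.append(point(t))
            s = t
        return np.asarray(pts), s

    c0 = total / (n_nodes - 1)
    _, end0 = march(c0)
    c1 = c0 * total / max(end0, 1e-12)
    _, end1 = march(c1)
    for _ in range(20):
        if abs(end1 - total) < 1e-12 * total or end1 == end0:
            break
        c0, c1 = c1, c1 + (total - end1) * (c1 - c0) / (end1 - end0)
        end0 = end1
        _, end1 = march(c1)
    pts, _ = march(c1)
    return pts


def natural_shape(program: ShapeProgram, spec: CoilSpec) -> NaturalShape:
    """Generate the imprinted natural centerline for a coil.

    The natural shape is parametrized by a twist-free Bishop frame, so its
    natural twist vanishes identically; natural curvatures are extracted
    with the same discrete operators used on the deformed rod.
    """
    L = spec.length
    n = program.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if program.kind == "straight":
        s = np.linspace(0.0, L, n)
        pts = np.column_stack([s, np.zeros(n), np.zeros(n)])
        return NaturalShape.from_vertices(pts)
    if program.kind == "helix":
        r = spec.D3 / 2.0
        spacing = program.loop_spacing if program.loop_spacing is not None else 1.2 * spec.D2
        c = spacing / (2.0 * np.pi)
        w = np.sqrt(r**2 + c**2)
        s = np.linspace(0.0, L, n)
        u = s / w
        pts = np.column_stack([r * np.cos(u), r * np.sin(u), c * u])
        return NaturalShape.from_vertices(pts)
    # complex3d: loops of varying orientation on a sphere of diameter D3.
    # A frozen parametric reference: a spherical spiral whose axis
    # precesses, giving the alternating-loop character of 3D framing
    # coils.
    rs = spec.D3 / 2.0
    n_dense = max(200 * 8, 40 * n)
    u = np.linspace(0.0, 1.0, n_dense)
    n_loops = max(3, int(round(L / (np.pi * spec.D3))))
    ang = 2 * np.pi * n_loops * u
    tilt = 0.9 * np.sin(2 * np.pi * u * 1.5)
    lat = 0.35 * np.pi * np.sin(2 * np.pi * u * 2.0 + 0.7)
    dirs = np.column_stack(
        [
            np.cos(ang) * np.cos(lat),
            np.sin(ang) * np.cos(lat) * np.cos(tilt) - np.sin(lat) * np.sin(tilt),
            np.sin(ang) * np.cos(lat) * np.sin(tilt) + np.sin(lat) * np.cos(tilt),
        ]
    )
    dense = rs * dirs
    # rescale the dense curve to total length L
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    dense *= L / seg.sum()
    pts = _resample_constant_chord(dense, n)
    return NaturalShape.from_vertices(pts)


def perturb_catheter_tip(
    catheter: CatheterSpline,
    radius: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> CatheterSpline:
    """Translate the catheter tip control point by a uniform-in-ball
    offset of the given radius (insertion-position uncertainty)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if radius == 0.0:
        offset = np.zeros(3)
    else:
        while True:
            offset = rng.uniform(-1.0, 1.0, 3)
            if np.dot(offset, offset) <= 1.0:
                break
        offset = offset * radius
    cps = catheter.control_points.copy()
    cps[2] = cps[2] + offset
    return CatheterSpline(cps, tube_radius=catheter.tube_radius, n_samples=catheter.n_samples)
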