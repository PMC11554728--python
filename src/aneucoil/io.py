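"""Plain-text output writers: legacy VTK, CSV summaries, JSON dumps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "write_vtk_polyline",
    "write_voxel_vtk",
    "write_voxel_json",
    "write_centerline_csv",
    "write_stretch_csv",
    "write_diagnostics_csv",
]


def write_vtk_polyline(path: str | Path, vertices: np.ndarray, scalars: np.ndarray | None = None, scalar_name: str = "arclength") -> None:
    """Legacy-VTK polyline (ASCII) of a coil centerline."""
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    n = len(vertices)
    lines = [
        "# vtk DataFile Version 3.0",
        "aneucoil centerline",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    lines += [f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}" for p in vertices]
    if n >= 2:
        lines.append(f"LINES 1 {n + 1}")
        lines.append(" ".join([str(n)] + [str(i) for i in range(n)]))
    if scalars is None and n:
        seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1) if n > 1 else np.zeros(0)
        scalars = np.concatenate([[0.0], np.cumsum(seg)])
    if scalars is not None and n:
        lines.append(f"POINT_DATA {n}")
        lines.append(f"SCALARS {scalar_name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{s:.8g}" for s in np.asarray(scalars, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_voxel_vtk(path: str | Path, field) -> None:
    """Voxel field as legacy-VTK structured points (ASCII)."""
    h = field.voxel_size
    n = field.n_voxels
    lines = [
        "# vtk DataFile Version 3.0",
        "aneucoil voxel field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {n} {n} {n}",
        f"ORIGIN {field.origin[0]:.8g} {field.origin[1]:.8g} {field.origin[2]:.8g}",
        f"SPACING {h:.8g} {h:.8g} {h:.8g}",
        f"POINT_DATA {n**3}",
        "SCALARS coil float 1",
        "LOOKUP_TABLE default",
    ]
    # VTK structured points iterate x fastest
    vals = np.transpose(field.values, (2, 1, 0)).ravel()
    lines += [f"{v:.6g}" for v in vals]
    Path(path).write_text("\n".join(lines) + "\n")


def write_voxel_json(path: str | Path, field) -> None:
    """JSON header + flat value list (C order over i, j, k)."""
    obj = {
        "origin_mm": [float(x) for x in field.origin],
        "edge_length_mm": float(field.edge_length),
        "n_voxels": int(field.n_voxels),
        "order": "C (i fastest last)",
        "values": [float(v) for v in field.values.ravel()],
    }
    Path(path).write_text(json.dumps(obj))


def read_voxel_json(path: str | Path):
    from aneucoil.occlusion import VoxelField

    obj = json.loads(Path(path).read_text())
    n = int(obj["n_voxels"])
    return VoxelField(
        np.asarray(obj["origin_mm"], dtype=float),
        float(obj["edge_length_mm"]),
        n,
        np.asarray(obj["values"], dtype=float).reshape(n, n, n),
    )


def write_centerline_csv(path: str | Path, deployment) -> None:
    """Deployed state as a columnar table: coil id, vertex position,
    velocity, edge angle (trailing edge), release step."""
    rows = ["coil,node,x_mm,y_mm,z_mm,vx_mm_s,vy_mm_s,vz_mm_s,phi_rad,release_step"]
    for c, st in enumerate(deployment.states):
        for i in range(st.n_vertices):
            phi = st.edge_angles[i] if i < st.n_vertices - 1 else np.nan
            v = st.vertices[i]
            w = st.velocities[i]
            rows.append(
                f"{c},{i},{v[0]:.8g},{v[1]:.8g},{v[2]:.8g},"
                f"{w[0]:.8g},{w[1]:.8g},{w[2]:.8g},{phi:.8g},{st.release_step[i]}"
            )
    Path(path).write_text("\n".join(rows) + "\n")


def write_stretch_csv(path: str | Path, stats) -> None:
    rows = [
        "edge,time_mean_rel_stretch,time_variance",
        *(
            f"{i},{m:.8g},{v:.8g}"
            for i, (m, v) in enumerate(zip(stats.per_edge_mean, stats.per_edge_var))
        ),
        f"# mean_stretch_percent,{stats.mean_stretch_percent:.6g}",
        f"# mean_stretch_std_percent,{stats.mean_stretch_std_percent:.6g}",
        f"# total_extension_percent,{stats.total_extension_percent:.6g}",
    ]
    Path(path).write_text("\n".join(rows) + "\n")


def write_diagnostics_csv(path: str | Path, diagnostics: dict) -> None:
    cols = diagnostics.get("history_columns", [])
    rows = [",".join(cols)]
    for rec in diagnostics.get("history", []):
        rows.append(",".join(f"{x:.8g}" if isinstance(x, float) else str(x) for x in rec))
    rows.append(f"# max_friction_cap_ratio,{diagnostics.get('max_friction_cap_ratio', 0):.8g}")
    rows.append(f"# max_penetration,{diagnostics.get('max_penetration', 0):.8g}")
    Path(path).write_text("\n".join(rows) + "\n")
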