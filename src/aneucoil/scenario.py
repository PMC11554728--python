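"""Reproducible scenario running: configs, seeding, outputs, manifests.

A scenario bundles everything one deployment study needs: the geometry
source (synthetic-dome parameters or a mesh file), an ordered list of
coil specifications with their shape programs, the catheter, simulation
and occlusion settings, and a single seed from which all randomness
(geometry bumps, catheter-tip perturbation, sweep sampling) flows through
named substreams.  Scenarios serialize to a YAML file whose keys carry
explicit units; re-running a serialized scenario reproduces its outputs
bit-identically on the same build.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from aneucoil import __version__
from aneucoil.dynamics import (
    DeploymentResult,
    SimulationConfig,
    coil_length_for_packing,
    run_deployment,
)
from aneucoil.geometry import (
    AneurysmDomain,
    CatheterSpline,
    ShapeProgram,
    cut_at_neck,
    load_mesh,
    make_synthetic_aneurysm,
    natural_shape,
    perturb_catheter_tip,
)
from aneucoil.occlusion import (
    OcclusionReport,
    bounding_cube,
    make_report,
    partition_regions,
    voxelize_coil,
    VoxelField,
)
from aneucoil.rod import CoilSpec

__all__ = [
    "Scenario",
    "ScenarioResult",
    "reference_dome_scenario",
    "default_catheter",
    "run_scenario",
]

_SUBSTREAMS = {"geometry": 1, "catheter": 2, "sweep": 3}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(max(_SUBSTREAMS.values()) + 1)[_SUBSTREAMS[name]])


@dataclass
class Scenario:
    """Serializable description of one deployment study."""

    geometry: dict = field(
        default_factory=lambda: {
            "kind": "synthetic",
            "dome_radius_mm": 2.5,
            "neck_radius_mm": 1.0,
            "parent_radius_mm": 1.5,
            "resolution": 28,
            "bump_amplitude": 0.0,
        }
    )
    coils: list = field(
        default_factory=lambda: [
            {
                "D1_um": 50.0,
                "D2_um": 305.0,
                "D3_mm": 2.0,
                "E_w_GPa": 168.0,
                "mu_w": 0.38,
                "pitch": 1.1,
                "alpha": 0.1,
                "shape": "helix",
                "n_nodes": 300,
                "length_mm": None,
            }
        ]
    )
    catheter: dict = field(
        default_factory=lambda: {
            "control_points_mm": None,
            "tube_radius_mm": 0.25,
            "tip_perturbation_mm": 0.0,
        }
    )
    simulation: dict = field(
        default_factory=lambda: {
            "v_push_mm_s": 250.0,
            "target_packing_density": 0.15,
            "dt_s": None,
            "post_swap_fraction": 0.10,
        }
    )
    occlusion: dict = field(default_factory=lambda: {"n_voxels": 70})
    output_dir: str | None = None
    seed: int = 0

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        data = yaml.safe_load(Path(path).read_text())
        sc = cls()
        for key in ("geometry", "coils", "catheter", "simulation", "occlusion"):
            if key in data and data[key] is not None:
                if isinstance(getattr(sc, key), dict):
                    getattr(sc, key).update(data[key])
                else:
                    setattr(sc, key, data[key])
        sc.output_dir = data.get("output_dir", sc.output_dir)
        sc.seed = int(data.get("seed", sc.seed))
        return sc

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- materialization --------------------------------------------------

    def build_domain(self) -> AneurysmDomain:
        g = self.geometry
        if g.get("kind", "synthetic") == "synthetic":
            rng = _substream(self.seed, "geometry")
            return make_synthetic_aneurysm(
                dome_radius=g.get("dome_radius_mm", 2.5),
                neck_radius=g.get("neck_radius_mm", 1.0),
                parent_radius=g.get("parent_radius_mm", 1.5),
                resolution=int(g.get("resolution", 28)),
                seed=int(rng.integers(0, 2**31 - 1)),
                bump_amplitude=g.get("bump_amplitude", 0.0),
            )
        vessel = load_mesh(g["vessel_path_mm"])
        point = np.asarray(g["neck_plane_point_mm"], dtype=float)
        normal = np.asarray(g["neck_plane_normal"], dtype=float)
        dome = cut_at_neck(vessel, point, normal)
        return AneurysmDomain(
            dome_mesh=dome,
            vessel_mesh=vessel,
            neck_plane_point=point,
            neck_plane_normal=normal,
            neck_radius=float(g["neck_radius_mm"]),
        )

    def build_coils(self, domain: AneurysmDomain) -> list[tuple[CoilSpec, object]]:
        sim = self.simulation
        out = []
        for c in self.coils:
            spec = CoilSpec(
                D1=c.get("D1_um", 50.0) / 1000.0,
                D2=c.get("D2_um", 305.0) / 1000.0,
                D3=c.get("D3_mm", 2.0),
                E_w=c.get("E_w_GPa", 168.0) * 1e9,
                mu_w=c.get("mu_w", 0.38),
                pitch=c.get("pitch", 1.1),
                alpha=c.get("alpha", 0.1),
            )
            length = c.get("length_mm")
            if length is None:
                pd = sim.get("target_packing_density") or 0.15
                length = coil_length_for_packing(domain, spec, pd) / max(len(self.coils), 1)
            spec = replace(spec, length=float(length))
            program = ShapeProgram(
                kind=c.get("shape", "helix"),
                n_nodes=int(c.get("n_nodes", 300)),
                loop_spacing=c.get("loop_spacing_mm"),
            )
            out.append((spec, natural_shape(program, spec)))
        return out

    def build_catheter(self, domain: AneurysmDomain) -> CatheterSpline:
        cp = self.catheter.get("control_points_mm")
        if cp is None:
            cath = default_catheter(domain, tube_radius=self.catheter.get("tube_radius_mm", 0.25))
        else:
            cath = CatheterSpline(
                np.asarray(cp, dtype=float),
                tube_radius=self.catheter.get("tube_radius_mm", 0.25),
            )
        pert = self.catheter.get("tip_perturbation_mm", 0.0)
        if pert:
            cath = perturb_catheter_tip(cath, pert, _substream(self.seed, "catheter"))
        return cath

    def build_sim_config(self) -> SimulationConfig:
        s = self.simulation
        return SimulationConfig(
            dt=s.get("dt_s"),
            v_push=s.get("v_push_mm_s", 250.0),
            post_swap_fraction=s.get("post_swap_fraction", 0.10),
            target_packing_density=s.get("target_packing_density"),
            seed=self.seed,
            record_every=int(s.get("record_every", 0)),
        )


def default_catheter(domain: AneurysmDomain, tube_radius: float = 0.25, reach: float = 0.8) -> CatheterSpline:
    """Catheter along the neck normal, tip ``reach`` mm inside the dome."""
    n = domain.neck_plane_normal
    p = np.asarray(domain.neck_centroid, dtype=float)
    cps = np.array([p - 5.0 * n, p - 2.5 * n, p + reach * n])
    return CatheterSpline(cps, tube_radius=tube_radius)


def reference_dome_scenario(
    alpha: float = 0.1,
    packing_density: float = 0.15,
    n_nodes: int = 300,
    seed: int = 0,
    v_push: float = 250.0,
    tip_perturbation: float = 0.0,
):
    """The synthetic-dome helix-coil study conditions.

    Spherical dome of radius 2.5 mm with a 1 mm neck; helix coil with
    D1 = 50 um, D2 = 305 um, D3 = 2 mm sized to the target packing
    density; catheter entering through the neck.  Returns
    ``(domain, coils, catheter, config)`` ready for
    :func:`aneucoil.dynamics.run_deployment`.
    """
    domain = make_synthetic_aneurysm(dome_radius=2.5, neck_radius=1.0)
    spec = CoilSpec(D1=0.05, D2=0.305, D3=2.0, alpha=alpha)
    L = coil_length_for_packing(domain, spec, packing_density)
    spec = replace(spec, length=L)
    nat = natural_shape(ShapeProgram("helix", n_nodes=n_nodes), spec)
    catheter = default_catheter(domain)
    if tip_perturbation:
        catheter = perturb_catheter_tip(catheter, tip_perturbation, np.random.default_rng(seed))
    config = SimulationConfig(v_push=v_push, seed=seed, target_packing_density=packing_density)
    return domain, [(spec, nat)], catheter, config


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    deployment: DeploymentResult
    voxel_field: VoxelField
    report: OcclusionReport
    manifest: dict


def run_scenario(scenario: Scenario, write: bool = True) -> ScenarioResult:
    """Run a scenario end to end: deploy, voxelize, partition, classify.

    With ``write`` and an ``output_dir``, emits the deployed centerline
    (CSV + VTK polyline), the voxel field (legacy VTK + JSON header with
    raw values), the occlusion report (JSON), stretch diagnostics (CSV)
    and a manifest with the config hash, seed and package versions.
    """
    from aneucoil import io as aio

    domain = scenario.build_domain()
    coils = scenario.build_coils(domain)
    catheter = scenario.build_catheter(domain)
    config = scenario.build_sim_config()
    dep = run_deployment(domain, coils, catheter, config)

    origin, a = bounding_cube(domain.dome_mesh)
    n_vox = int(scenario.occlusion.get("n_voxels", 70))
    centerline = dep.centerline
    fld = voxelize_coil(centerline, coils[0][0].D2, origin, a, n_vox)
    part = partition_regions(domain, n_voxels=n_vox)
    report = make_report(fld, part, metadata={"packing_density_target": scenario.simulation.get("target_packing_density")})

    manifest = {
        "config_hash": scenario.config_hash(),
        "seed": scenario.seed,
        "versions": _versions(),
        "n_steps": dep.n_steps,
        "dt_s": dep.dt,
        "inserted_length_mm": dep.inserted_length,
        "class": report.label,
        "parameter_provenance": _provenance(scenario),
    }
    result = ScenarioResult(dep, fld, report, manifest)
    if write and scenario.output_dir:
        out = Path(scenario.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        aio.write_centerline_csv(out / "centerline.csv", dep)
        aio.write_vtk_polyline(out / "coil.vtk", centerline)
        aio.write_voxel_vtk(out / "voxels.vtk", fld)
        aio.write_voxel_json(out / "voxels.json", fld)
        (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
        aio.write_stretch_csv(out / "stretch.csv", dep.stretch)
        aio.write_diagnostics_csv(out / "diagnostics.csv", dep.diagnostics)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for k, (step, verts) in enumerate(dep.trajectory):
            aio.write_vtk_polyline(out / f"trajectory_{step:08d}.vtk", verts)
    return result


def _versions() -> dict:
    import numpy
    import scipy
    import trimesh as tm

    return {
        "aneucoil": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "trimesh": tm.__version__,
    }


def _provenance(scenario: Scenario) -> dict:
    """Provenance tag for every defaulted physical parameter."""
    prov = {
        "E_w_GPa": "paper" if all(c.get("E_w_GPa", 168.0) == 168.0 for c in scenario.coils) else "user",
        "pitch": "paper",
        "mu_w": "calibrated",
        "alpha_reference_stiffness": "calibrated",
        "friction_coefficients": "calibrated",
        "contact_springs": "calibrated",
        "damping": "calibrated",
        "dt_s": "user" if scenario.simulation.get("dt_s") else "calibrated",
        "v_push_mm_s": "user" if "v_push_mm_s" in scenario.simulation else "calibrated",
        "voxels_per_axis": "paper",
        "classifier_thresholds": "paper",
        "neck_sphere": "calibrated",
    }
    return prov
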