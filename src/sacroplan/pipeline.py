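"""End-to-end orchestration: phantom -> calibration -> geometry -> planning
-> FE comparison -> drill guide -> accuracy audit.

Every stage writes its artifacts into the run directory and contributes to
one summary JSON. A single seed governs all randomness; per-stage sub-seeds
are derived from it, so a rerun with the same config reproduces the summary
bit for bit (timings are logged separately).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import accuracy as acc
from . import fesolve, geometry, materials, phantom, screw as screw_mod
from .femesh import define_node_sets, tetrahedralize
from .guide import GuideSpec, build_guide, extract_contact_patch
from .spatial import Line3D, RigidTransform, rotation_about_axis

log = logging.getLogger("sacroplan")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    voxel_spacing: float = 0.6
    scale: float = 1.0
    noise_sd: float = 15.0
    rod_densities: list[float] = Field(default=[0.0, 0.05, 0.10, 0.15, 0.20])
    with_fragment: bool = True
    save_volume: bool = False


class CalibrationConfig(_Strict):
    erode_voxels: int = 1


class MaterialConfig(_Strict):
    e_min_mpa: float = 0.01
    poisson: float = 0.3
    metal_hu: float = 2000.0
    strategy: str = "voxel_mean"


class GeometryConfig(_Strict):
    bone_lower_hu: float = 200.0
    bone_upper_hu: float = 1400.0
    smooth_iterations: int = 6
    smooth_factor: float = 0.7
    remesh_target_edge: Optional[float] = None   # None skips remeshing
    sharp_angle_deg: float = 60.0
    clearance_mm: float = 0.5


class FEConfig(_Strict):
    element_size: float = 2.2
    load_n: float = 500.0
    caudal_fraction: float = 1.0 / 3.0
    sweep_sizes: Optional[list[float]] = None
    convergence_tol: float = 0.02
    solver: str = "direct"


class GuideConfig(_Strict):
    enabled: bool = True
    tube_inner_diameter: float = 2.7
    tube_outer_diameter: float = 7.0
    tube_length: float = 22.0
    shell_thickness: float = 3.0
    mc_pitch: float = 0.45


class EvaluationConfig(_Strict):
    enabled: bool = True
    tilt_deg: dict[str, float] = Field(default={"S1": 1.0, "ALA": 0.7})
    pose_angle_deg: float = 10.0
    pose_translation_mm: float = 8.0
    landmark_noise_sd: float = 0.2
    metal_hu: float = 1500.0
    drill_diameter: float = 2.5


class RunConfig(_Strict):
    seed: int = 1
    output_dir: str = "runs/demo"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    material: MaterialConfig = Field(default_factory=MaterialConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    fe: FEConfig = Field(default_factory=FEConfig)
    guide: GuideConfig = Field(default_factory=GuideConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _phantom_spec(cfg: RunConfig) -> phantom.PhantomSpec:
    p = cfg.phantom
    return phantom.PhantomSpec(
        voxel_spacing=p.voxel_spacing,
        rod_densities=tuple(p.rod_densities),
        bone_shape_params=phantom.default_bone_shape(p.scale),
        with_fragment=p.with_fragment,
        noise_sd=p.noise_sd,
        seed=cfg.seed,
    )


def build_fe_model(assembly, plan, volume, model, size, caudal_fraction=1.0 / 3.0,
                   metal_hu=2000.0, strategy="voxel_mean"):
    """Mesh one single-screw assembly, assign materials, define node sets."""
    from .screw import Assembly

    import trimesh

    from .spatial import RigidTransform

    # FE idealization of the screw: the smooth shaft, extended dorsally by
    # the head height as the loading stub. The wide tulip head is cosmetic
    # and would spuriously bond to the dorsal cortex on a voxel grid.
    s = plan.screw
    stub = s.head_height
    total = s.length + stub
    shaft = trimesh.creation.cylinder(radius=s.diameter / 2, height=total,
                                      sections=32)
    z = np.array([0.0, 0.0, 1.0])
    R = trimesh.geometry.align_vectors(z, plan.direction)
    shaft.apply_transform(R)
    center = plan.entry + (s.length - stub) / 2 * plan.direction
    shaft.apply_translation(center)
    single = Assembly(bone=assembly.bone, fragment=assembly.fragment,
                      screws={plan.label: shaft},
                      plans={plan.label: plan})
    reinforce = [(plan.entry - stub * plan.direction, plan.direction,
                  total, s.diameter / 2)]
    mesh = tetrahedralize(single, size, reinforce_axes=reinforce)
    mesh, _report = materials.assign_element_materials(
        mesh, volume, model, metal_hu=metal_hu, strategy=strategy)
    head_h = plan.screw.head_height
    sets = define_node_sets(
        mesh, caudal_fraction=caudal_fraction,
        head_spec={"axis_point": plan.entry, "axis_dir": -plan.direction,
                   "t_range": (-1.0, head_h + 2.0),
                   "measure_range": (0.0, head_h)})
    return mesh, sets


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    t_start = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))
    timings: dict[str, float] = {}
    summary: dict = {"seed": config.seed}
    rng = np.random.default_rng(config.seed)

    def stage(name):
        log.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    # 1. phantom ----------------------------------------------------------
    stage("phantom")
    spec = _phantom_spec(config)
    volume, truth = phantom.generate_phantom(spec)
    if config.phantom.save_volume:
        volume.save(out / "phantom.nii.gz")
    (out / "phantom_truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))
    done("phantom")

    # 2. calibration ------------------------------------------------------
    stage("calibration")
    samples = materials.sample_rods(volume, truth.rods,
                                    erode_voxels=config.calibration.erode_voxels)
    fitted_law, diag = materials.fit_hu_to_density(samples)
    model = materials.DensityModulusModel(
        hu_to_density=fitted_law,
        e_min=config.material.e_min_mpa,
        poisson=config.material.poisson)
    model.save(out / "material_model.json")
    summary["calibration"] = {
        "fitted": fitted_law.to_dict(), "true": truth.true_hu_to_density.to_dict(),
        "r_squared": diag["r_squared"],
        "slope_rel_err": abs(fitted_law.slope / truth.true_hu_to_density.slope - 1.0),
    }
    done("calibration")

    # 3. geometry ---------------------------------------------------------
    stage("geometry")
    g = config.geometry
    bone_mask = geometry.segment(volume, g.bone_lower_hu, g.bone_upper_hu)
    bone_surface = geometry.extract_surface(bone_mask)
    bone_surface = geometry.smooth_surface(bone_surface, g.smooth_iterations,
                                           g.smooth_factor)
    if g.remesh_target_edge:
        bone_surface = geometry.remesh_uniform(bone_surface, g.remesh_target_edge,
                                               g.sharp_angle_deg)
    bone_surface.export(out / "bone.stl")
    fragment_surface = None
    if config.phantom.with_fragment:
        frag_mask = geometry.segment(volume, config.material.metal_hu)
        fragment_surface = geometry.extract_surface(frag_mask)
        fragment_surface.export(out / "fragment.stl")
    summary["geometry"] = {
        "bone_voxels": bone_mask.voxel_count(),
        "bone_surface_watertight": bool(bone_surface.is_watertight),
        "bone_volume_mm3": float(bone_surface.volume),
    }
    done("geometry")

    # 4. planning ---------------------------------------------------------
    stage("planning")
    scale = config.phantom.scale
    screw_spec = screw_mod.ScrewSpec().scaled(scale)
    assembly = screw_mod.Assembly(bone=bone_surface, fragment=fragment_surface)
    plans = {}
    summary["planning"] = {}
    for label, axis in truth.true_axes.items():
        plan = screw_mod.TrajectoryPlan(label, axis.point, axis.direction, screw_spec)
        assembly, rep = screw_mod.place_screw(assembly, plan)
        plans[label] = plan
        entry = {"placement": rep}
        if fragment_surface is not None:
            entry["collision"] = screw_mod.check_collision(plan, fragment_surface,
                                                           clearance=g.clearance_mm)
        summary["planning"][label] = entry
    (out / "plans.json").write_text(json.dumps(
        {k: p.to_dict() for k, p in plans.items()}, indent=2))
    done("planning")

    # 5. FE comparison ----------------------------------------------------
    stage("fe")
    load_cases = {}
    summary["fe"] = {}
    for label, plan in plans.items():
        load = fesolve.LoadCase(config.fe.load_n, -plan.direction)  # pull-out
        load_cases[label] = load
        mesh, sets = build_fe_model(assembly, plan, volume, model,
                                    config.fe.element_size,
                                    caudal_fraction=config.fe.caudal_fraction,
                                    metal_hu=config.material.metal_hu,
                                    strategy=config.material.strategy)
        res = fesolve.solve_static(mesh, sets, load, solver=config.fe.solver)
        fesolve.export_inp(mesh, sets, load, out / f"model_{label}.inp")
        summary["fe"][label] = {
            "n_elements": len(mesh.elements),
            "n_dof": res.diagnostics["n_dof"],
            "mean_u_head_mm": res.mean_u_head,
            "stiffness_n_per_mm": res.stiffness,
        }
    kS1 = summary["fe"].get("S1", {}).get("stiffness_n_per_mm")
    kALA = summary["fe"].get("ALA", {}).get("stiffness_n_per_mm")
    if kS1 and kALA:
        summary["fe"]["stiffness_ratio_convergent_over_divergent"] = kS1 / kALA
    done("fe")

    # 6. convergence sweep (optional) -------------------------------------
    if config.fe.sweep_sizes:
        stage("convergence")
        summary["convergence"] = {}
        for label, plan in plans.items():
            factory = lambda size, p=plan: build_fe_model(
                assembly, p, volume, model, size,
                caudal_fraction=config.fe.caudal_fraction,
                metal_hu=config.material.metal_hu,
                strategy=config.material.strategy)
            table = fesolve.convergence_sweep(factory, config.fe.sweep_sizes,
                                              load_cases[label],
                                              tol=config.fe.convergence_tol)
            table.to_csv(out / f"convergence_{label}.csv", index=False)
            summary["convergence"][label] = json.loads(
                table.drop(columns=["solve_time_s"]).to_json(orient="records"))
        done("convergence")

    # 7. drill guide ------------------------------------------------------
    if config.guide.enabled:
        stage("guide")
        gc = config.guide
        patch = extract_contact_patch(bone_surface)
        template = build_guide(patch, plans.values(), GuideSpec(
            tube_inner_diameter=gc.tube_inner_diameter,
            tube_outer_diameter=gc.tube_outer_diameter,
            tube_length=gc.tube_length, shell_thickness=gc.shell_thickness,
            mc_pitch=gc.mc_pitch))
        template.export(out / "guide.stl")
        summary["guide"] = {
            "watertight": bool(template.is_watertight),
            "genus": int((2 - template.euler_number) // 2),
            "n_faces": len(template.faces),
        }
        done("guide")

    # 8. accuracy audit ---------------------------------------------------
    if config.evaluation.enabled:
        stage("evaluation")
        ev = config.evaluation
        realized = {}
        for label, plan in plans.items():
            tilt = ev.tilt_deg.get(label, 0.0)
            perp = np.cross(plan.direction, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(plan.direction, [1.0, 0.0, 0.0])
            R = rotation_about_axis(perp, tilt)
            realized[label] = Line3D(plan.entry, R @ plan.direction)
        pose = RigidTransform.from_axis_angle(
            rng.normal(size=3), float(rng.uniform(-ev.pose_angle_deg, ev.pose_angle_deg)),
            rng.uniform(-ev.pose_translation_mm, ev.pose_translation_mm, 3),
            center=bone_surface.centroid)
        postdrill = phantom.simulate_postdrill_volume(
            truth, realized, pose, drill_diameter=ev.drill_diameter,
            seed=int(rng.integers(2**31)))
        lms = (phantom.posed_landmarks(truth, pose, noise_sd=ev.landmark_noise_sd,
                                       seed=int(rng.integers(2**31))),
               truth.landmarks)
        report = acc.evaluate_drilling(plans, postdrill, bone_surface, lms,
                                       metal_hu=ev.metal_hu,
                                       drill_diameter=ev.drill_diameter)
        (out / "accuracy_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out / "accuracy_report.txt").write_text(report.summary() + "\n")
        summary["accuracy"] = report.to_dict()
        summary["accuracy"]["applied_tilt_deg"] = ev.tilt_deg
        done("evaluation")

    timings["total"] = time.perf_counter() - t_start
    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("run complete: %s", out)
    return out
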