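"""Parametric pedicle screw, trajectory planning and fragment-clearance checks.

The screw is a surface of revolution: a cylindrical shaft (tip at the local
origin, axis +z) topped by a wider monoaxial head. Thread rendering is
optional and for visualization only — the FE idealization bonds a smooth
shaft to the bone, so threads are omitted from simulation geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

import trimesh

from .meshquery import MeshQuery
from .spatial import Line3D, RigidTransform

__all__ = ["ScrewSpec", "TrajectoryPlan", "Assembly", "make_screw", "place_screw",
           "check_collision", "screw_sdf"]


@dataclass(frozen=True)
class ScrewSpec:
    """Monoaxial pedicle screw dimensions (mm)."""

    length: float = 45.0
    diameter: float = 6.5
    head_diameter: float = 11.0
    head_height: float = 10.0
    thread: bool = False
    thread_pitch: float = 2.75
    thread_depth: float = 0.8

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("screw length and diameter must be positive")
        if self.head_diameter <= 0 or self.head_height <= 0:
            raise ValueError("head dimensions must be positive")

    def scaled(self, s: float) -> "ScrewSpec":
        return replace(self, length=self.length * s, diameter=self.diameter * s,
                       head_diameter=self.head_diameter * s,
                       head_height=self.head_height * s)


@dataclass
class TrajectoryPlan:
    """A labelled screw axis: entry point on the bone plus unit direction
    (pointing into the bone)."""

    label: str
    entry: np.ndarray
    direction: np.ndarray
    screw: ScrewSpec = field(default_factory=ScrewSpec)

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, float).reshape(3)
        d = np.asarray(self.direction, float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be nonzero")
        self.direction = d / n

    @property
    def axis(self) -> Line3D:
        return Line3D(self.entry, self.direction)

    def tip(self) -> np.ndarray:
        return self.entry + self.screw.length * self.direction

    def to_dict(self) -> dict:
        return {"label": self.label, "entry": self.entry.tolist(),
                "direction": self.direction.tolist(),
                "length": self.screw.length, "diameter": self.screw.diameter}

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryPlan":
        spec = ScrewSpec(length=d.get("length", 45.0), diameter=d.get("diameter", 6.5))
        return cls(d["label"], np.asarray(d["entry"]), np.asarray(d["direction"]), spec)


@dataclass
class Assembly:
    """Bone + optional fragment + placed screw surfaces, with their plans."""

    bone: trimesh.Trimesh
    fragment: trimesh.Trimesh | None = None
    screws: dict = field(default_factory=dict)       # label -> Trimesh
    plans: dict = field(default_factory=dict)        # label -> TrajectoryPlan
    reports: dict = field(default_factory=dict)      # label -> placement report


def make_screw(spec: ScrewSpec, sections: int = 48) -> trimesh.Trimesh:
    """Watertight screw solid, tip at the origin, axis +z, head on top."""
    r = spec.diameter / 2.0
    rh = spec.head_diameter / 2.0
    L = spec.length
    tip_ch = min(1.5, 0.4 * L)  # small tip chamfer
    prof = [(0.0, 0.0), (r, tip_ch)]
    if spec.thread:
        zs = np.arange(tip_ch + spec.thread_pitch / 2, L - 1.0, spec.thread_pitch / 2)
        for i, z in enumerate(zs):
            rr = r if i % 2 else max(r - spec.thread_depth, 0.2 * r)
            prof.append((rr, z))
    prof += [(r, L), (rh, L), (rh, L + spec.head_height), (0.0, L + spec.head_height)]
    linestring = np.asarray(prof)  # (radius, z) pairs, revolved about +z
    mesh = trimesh.creation.revolve(linestring, sections=sections)
    mesh.process(validate=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def screw_pose(plan: TrajectoryPlan) -> RigidTransform:
    """Rigid transform taking the local screw (tip at origin, +z) to its
    planned pose: tip at entry + length * direction, head outside the bone."""
    z = np.array([0.0, 0.0, 1.0])
    target = -plan.direction
    v = np.cross(z, target)
    c = float(z @ target)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * (1 / (1 + c))
    return RigidTransform(R, plan.tip())


def place_screw(assembly: Assembly, plan: TrajectoryPlan,
                sections: int = 48) -> tuple[Assembly, dict]:
    """Insert the planned screw into the assembly and characterize the path.

    The report counts cortex crossings along the screw segment (the entry
    crossing included), so bicortical placement shows >= 2 crossings and
    monocortical exactly 1, and measures the inserted length (the part of
    the shaft inside the bone).
    """
    q = MeshQuery(assembly.bone)
    L = plan.screw.length
    eps = 0.25
    hits = q.ray_hits(plan.entry - eps * plan.direction, plan.direction,
                      t_min=0.0, t_max=L + eps)
    if len(hits) == 0:
        raise ValueError(f"plan {plan.label!r}: axis does not intersect the bone")
    crossings = len(hits)
    # inserted length: measure the inside part of the screw segment
    ts = np.r_[0.0, hits, L + eps]
    inserted = 0.0
    state = bool(q.contains((plan.entry - eps * plan.direction)[None])[0])
    for a, b in zip(ts[:-1], ts[1:]):
        if state:
            inserted += b - a
        state = not state
    mesh = make_screw(plan.screw, sections=sections)
    pose = screw_pose(plan)
    mesh = mesh.copy()
    mesh.apply_transform(pose.matrix())
    assembly.screws[plan.label] = mesh
    assembly.plans[plan.label] = plan
    report = {
        "label": plan.label,
        "crossings": int(crossings),
        "bicortical": bool(crossings >= 2),
        "inserted_length_mm": float(inserted),
    }
    assembly.reports[plan.label] = report
    return assembly, report


def screw_sdf(plan: TrajectoryPlan, points: np.ndarray) -> np.ndarray:
    """Signed distance to the planned screw solid (negative inside);
    analytic union of the shaft and head cylinders."""
    pts = np.atleast_2d(points)
    d_shaft = _capped_cylinder_sdf(pts, plan.entry + plan.screw.length * plan.direction,
                                   -plan.direction, plan.screw.diameter / 2,
                                   plan.screw.length)
    head_base = plan.entry
    d_head = _capped_cylinder_sdf(pts, head_base, -plan.direction,
                                  plan.screw.head_diameter / 2, plan.screw.head_height)
    return np.minimum(d_shaft, d_head)


def _capped_cylinder_sdf(pts, base, direction, radius, length) -> np.ndarray:
    """SDF of a finite cylinder from ``base`` along ``direction``."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    v = pts - np.asarray(base, float)
    t = v @ d
    r = np.linalg.norm(v - np.outer(t, d), axis=1)
    dr = r - radius
    dz = np.maximum(-t, t - length)
    outside = np.sqrt(np.maximum(dr, 0) ** 2 + np.maximum(dz, 0) ** 2)
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    return np.where((dr > 0) | (dz > 0), outside, inside)


def check_collision(plan: TrajectoryPlan, fragment: trimesh.Trimesh,
                    clearance: float = 0.0) -> dict:
    """Minimum distance between the planned screw solid and the fragment.

    Passes iff the distance is >= clearance (touching surfaces at zero
    clearance pass by definition). Overlap is detected via fragment surface
    points falling inside the screw solid.
    """
    if not fragment.is_watertight:
        raise ValueError("fragment surface must be watertight")
    pts = np.vstack([fragment.vertices, fragment.triangles_center])
    sd = screw_sdf(plan, pts)
    min_sd = float(sd.min())
    overlap = min_sd < -1e-9
    distance = max(min_sd, 0.0)
    return {
        "label": plan.label,
        "distance_mm": distance,
        "overlap": bool(overlap),
        "pass": bool((not overlap) and distance >= clearance - 1e-9),
        "clearance_mm": clearance,
    }
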