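"""Synthetic QCT phantom: calibration rods, a sacrum-like bone, an embedded
broken-screw fragment, and post-drill scan simulation.

The bone stand-in is a parametric solid — an elliptic extrusion ("body")
with a flat cranial cap (the "endplate"), united with a lateral ellipsoid
wing (the "ala") — chosen so that two realistic screw corridors exist: a
convergent bicortical path through the body (entering the posterior cortex,
exiting the anterior cortex) and a divergent monocortical path into the
low-density ala. A five-rod calibration insert of known equivalent BMD sits
caudal to the bone, in-line with it, as in clinical QCT protocols.

HU values are produced by inverting a known ground-truth HU->density law,
so calibration recovery is exactly testable; metal (fragment, drill bits)
renders at a fixed saturated HU since only its geometric role matters.
Partial volume is approximated by 2x supersampling per axis. All randomness
flows from one seeded generator recorded in the truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

import trimesh

from .materials import LinearLaw
from .meshutil import marching_mesh
from .spatial import Line3D, RigidTransform
from .volume import CtVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "default_bone_shape",
    "generate_phantom",
    "simulate_postdrill_volume",
    "posed_landmarks",
]

TRUE_HU_TO_DENSITY = LinearLaw(-0.0829, 0.0026, "HU", "rho_app[g/cm3]")


def default_bone_shape(scale: float = 1.0) -> dict:
    """Parametric sacrum stand-in. ``scale`` shrinks the whole scene
    (useful for fast finite-element studies on the same topology)."""
    s = float(scale)
    return {
        "scale": s,
        "body_a": 25.0 * s,          # half-axis, left-right (mm)
        "body_b": 18.0 * s,          # half-axis, antero-posterior (mm)
        "body_z0": 0.0,
        "body_z1": 40.0 * s,         # cranial cap = "endplate"
        "ala_center": (30.0 * s, 0.0, 30.0 * s),
        "ala_radii": (18.0 * s, 12.0 * s, 9.0 * s),
        "cortical_thickness": max(1.5 * s, 1.0),
        # planned corridors: direction + a point known to lie inside the bone;
        # anchors chosen so the two axes stay well separated near their entries
        "s1_direction": (0.25, 0.95, -0.08),
        "s1_anchor": (-6.0 * s, 0.0, 16.0 * s),
        "ala_direction": (0.85, 0.45, 0.15),
        "ala_anchor": (10.0 * s, -4.0 * s, 33.0 * s),
        # fragment of the old broken screw, lodged in the body
        "fragment_center": (6.0 * s, 3.0 * s, 15.0 * s),
        "fragment_axis": (0.15, 0.99, 0.0),
        "fragment_radius": 1.75,
        "fragment_length": 14.0 * s,
        # calibration insert
        "rod_radius": 4.0 * max(s, 0.75),
        "rod_length": 36.0 * max(s, 0.75),
        "rod_z": -12.0 * max(s, 0.75),
        "rod_x_extent": 28.0 * s,
    }


@dataclass
class PhantomSpec:
    """Generation parameters for one synthetic QCT scene."""

    voxel_spacing: float = 0.6                      # mm, isotropic
    rod_densities: tuple = (0.0, 0.05, 0.10, 0.15, 0.20)  # g/cm^3
    bone_shape_params: dict = field(default_factory=default_bone_shape)
    cortical_density: float = 1.2                   # g/cm^3
    trabecular_density_range: tuple = (0.08, 0.30)  # (ala, body) g/cm^3
    with_fragment: bool = True
    noise_sd: float = 15.0                          # HU
    seed: int = 0
    background_hu: float = -100.0
    metal_hu: float = 3000.0
    margin: float = 4.0                             # mm of air around the scene
    volume_origin: Optional[tuple] = None           # override auto-framing
    volume_shape: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        rods = np.asarray(self.rod_densities, float)
        if np.any(rods < 0):
            raise ValueError("rod densities must be non-negative")
        if np.any(np.diff(np.sort(rods)) <= 0):
            raise ValueError("rod densities must be distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def small(cls, scale: float = 0.55, voxel_spacing: float = 1.0, **kw) -> "PhantomSpec":
        """A geometrically scaled-down scene for fast FE studies."""
        return cls(voxel_spacing=voxel_spacing,
                   bone_shape_params=default_bone_shape(scale), **kw)


class Scene:
    """Exact analytic solid tests for the phantom geometry."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.p = spec.bone_shape_params

    # -- solids ------------------------------------------------------------

    def _body_contains(self, pts, shrink: float = 0.0) -> np.ndarray:
        p = self.p
        a = p["body_a"] - shrink
        b = p["body_b"] - shrink
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        return ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & \
            (z >= p["body_z0"] + shrink) & (z <= p["body_z1"] - shrink)

    def _ala_contains(self, pts, shrink: float = 0.0) -> np.ndarray:
        c = np.asarray(self.p["ala_center"])
        r = np.asarray(self.p["ala_radii"]) - shrink
        q = (pts - c) / r
        return np.einsum("ij,ij->i", q, q) <= 1.0

    def bone_contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return self._body_contains(pts) | self._ala_contains(pts)

    def interior_contains(self, pts: np.ndarray) -> np.ndarray:
        """Trabecular interior (bone minus the cortical shell)."""
        pts = np.atleast_2d(pts)
        t = self.p["cortical_thickness"]
        return self._body_contains(pts, t) | self._ala_contains(pts, t)

    def fragment_contains(self, pts: np.ndarray) -> np.ndarray:
        if not self.spec.with_fragment:
            return np.zeros(len(np.atleast_2d(pts)), bool)
        p = self.p
        return _cylinder_contains(pts, p["fragment_center"], p["fragment_axis"],
                                  p["fragment_radius"], p["fragment_length"])

    def rods(self) -> list:
        """(center, axis, radius, length, density) per calibration rod."""
        p = self.p
        xs = np.linspace(-p["rod_x_extent"], p["rod_x_extent"], len(self.spec.rod_densities))
        return [((float(x), 0.0, p["rod_z"]), (0.0, 1.0, 0.0),
                 p["rod_radius"], p["rod_length"], float(d))
                for x, d in zip(xs, np.sort(np.asarray(self.spec.rod_densities, float)))]

    def density(self, pts: np.ndarray) -> np.ndarray:
        """Apparent density field (g/cm^3); zero outside bone."""
        pts = np.atleast_2d(pts)
        rho = np.zeros(len(pts))
        bone = self.bone_contains(pts)
        rho[bone] = self.spec.cortical_density
        inner = self.interior_contains(pts)
        lo, hi = self.spec.trabecular_density_range
        # the ala interior is markedly less dense than the body, as in real sacra
        in_ala_core = self._ala_contains(pts, self.p["cortical_thickness"])
        rho[inner] = hi
        rho[inner & in_ala_core] = lo
        return rho

    # -- extents -----------------------------------------------------------

    def bone_bbox(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        c = np.asarray(p["ala_center"])
        r = np.asarray(p["ala_radii"])
        lo = np.minimum([-p["body_a"], -p["body_b"], p["body_z0"]], c - r)
        hi = np.maximum([p["body_a"], p["body_b"], p["body_z1"]], c + r)
        return lo, hi

    def scene_bbox(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.bone_bbox()
        p = self.p
        rod_lo = np.array([-p["rod_x_extent"] - p["rod_radius"],
                           -p["rod_length"] / 2, p["rod_z"] - p["rod_radius"]])
        rod_hi = np.array([p["rod_x_extent"] + p["rod_radius"],
                           p["rod_length"] / 2, p["rod_z"] + p["rod_radius"]])
        return np.minimum(lo, rod_lo), np.maximum(hi, rod_hi)

    def solid_volume(self, pitch: float = 0.25) -> float:
        """Numeric volume of the bone solid by fine-grid integration (mm^3)."""
        lo, hi = self.bone_bbox()
        axes = [np.arange(lo[a] + pitch / 2, hi[a], pitch) for a in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        return float(self.bone_contains(pts).sum()) * pitch**3

    # -- derived geometry ---------------------------------------------------

    def plan_axes(self) -> dict[str, Line3D]:
        """Planned screw axes with points at the bone entry."""
        p = self.p
        out = {}
        for label, dkey, akey in [("S1", "s1_direction", "s1_anchor"),
                                  ("ALA", "ala_direction", "ala_anchor")]:
            d = np.asarray(p[dkey], float)
            d = d / np.linalg.norm(d)
            entry = self._entry_point(np.asarray(p[akey], float), d)
            out[label] = Line3D(entry, d)
        return out

    def _entry_point(self, anchor: np.ndarray, direction: np.ndarray) -> np.ndarray:
        # march backwards out of the bone, then bisect the boundary crossing
        t_out = 0.0
        step = 2.0
        while self.bone_contains((anchor - (t_out + step) * direction)[None])[0]:
            t_out += step
            if t_out > 500:
                raise ValueError("anchor ray never leaves the bone")
        lo, hi = t_out, t_out + step  # inside at lo, outside at hi
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if self.bone_contains((anchor - mid * direction)[None])[0]:
                lo = mid
            else:
                hi = mid
        return anchor - 0.5 * (lo + hi) * direction

    def landmarks(self) -> np.ndarray:
        """Six registration landmarks on the caudal bone surface."""
        p = self.p
        zs = [p["body_z0"] + 0.10 * (p["body_z1"] - p["body_z0"]),
              p["body_z0"] + 0.25 * (p["body_z1"] - p["body_z0"])]
        pts = []
        for z, angles in zip(zs, [(200.0, 270.0, 340.0), (225.0, 270.0, 315.0)]):
            for ang in angles:
                th = np.deg2rad(ang)
                pts.append([p["body_a"] * np.cos(th), p["body_b"] * np.sin(th), z])
        return np.asarray(pts)

    def surface(self, which: str = "bone", pitch: float = 0.35) -> trimesh.Trimesh:
        """Watertight truth surface via a level-set marching cubes."""
        if which == "bone":
            f = self._bone_levelset
            lo, hi = self.bone_bbox()
        elif which == "fragment":
            if not self.spec.with_fragment:
                raise ValueError("phantom has no fragment")
            p = self.p
            c = np.asarray(p["fragment_center"], float)
            half = p["fragment_length"] / 2 + p["fragment_radius"] + 1
            lo, hi = c - half, c + half
            f = lambda q: _cylinder_quasi_sdf(q, p["fragment_center"], p["fragment_axis"],
                                              p["fragment_radius"], p["fragment_length"])
        else:
            raise ValueError(which)
        lo = lo - 2 * pitch
        hi = hi + 2 * pitch
        axes = [np.arange(lo[a], hi[a] + pitch, pitch) for a in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        vol = f(pts).reshape(X.shape)
        return marching_mesh(vol, 0.0, lo, pitch)

    def _bone_levelset(self, pts: np.ndarray) -> np.ndarray:
        p = self.p
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        re = np.sqrt((x / p["body_a"]) ** 2 + (y / p["body_b"]) ** 2)
        g_side = (re - 1.0) * min(p["body_a"], p["body_b"])
        body = np.maximum.reduce([g_side, p["body_z0"] - z, z - p["body_z1"]])
        c = np.asarray(p["ala_center"])
        r = np.asarray(p["ala_radii"])
        q = (pts - c) / r
        ala = (np.sqrt(np.einsum("ij,ij->i", q, q)) - 1.0) * float(r.min())
        return np.minimum(body, ala)


def _cylinder_contains(pts, center, axis, radius, length) -> np.ndarray:
    pts = np.atleast_2d(pts)
    c = np.asarray(center, float)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    v = pts - c
    t = v @ a
    r = np.linalg.norm(v - np.outer(t, a), axis=1)
    return (r <= radius) & (np.abs(t) <= length / 2)


def _cylinder_quasi_sdf(pts, center, axis, radius, length) -> np.ndarray:
    pts = np.atleast_2d(pts)
    c = np.asarray(center, float)
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    v = pts - c
    t = v @ a
    r = np.linalg.norm(v - np.outer(t, a), axis=1)
    return np.maximum(r - radius, np.abs(t) - length / 2)


@dataclass
class PhantomTruth:
    """Every generating parameter and derived ground-truth object."""

    spec: PhantomSpec
    scene: Scene
    true_hu_to_density: LinearLaw
    true_density_field: np.ndarray          # g/cm^3 per voxel (noise-free)
    true_axes: dict                         # label -> Line3D, at bone entry
    rods: list                              # (center, axis, radius, length, density)
    landmarks: np.ndarray                   # (6, 3) caudal surface points
    _surfaces: dict = field(default_factory=dict)

    def surface(self, which: str = "bone") -> trimesh.Trimesh:
        if which not in self._surfaces:
            self._surfaces[which] = self.scene.surface(which)
        return self._surfaces[which]

    @property
    def true_surfaces(self) -> dict:
        return {"bone": self.surface("bone"),
                **({"fragment": self.surface("fragment")} if self.spec.with_fragment else {})}

    def to_json_dict(self) -> dict:
        return {
            "voxel_spacing": self.spec.voxel_spacing,
            "rod_densities": list(np.sort(np.asarray(self.spec.rod_densities, float))),
            "bone_shape_params": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                                  for k, v in self.spec.bone_shape_params.items()},
            "noise_sd": self.spec.noise_sd,
            "seed": self.spec.seed,
            "true_hu_to_density": self.true_hu_to_density.to_dict(),
            "true_axes": {k: {"point": list(v.point), "direction": list(v.direction)}
                          for k, v in self.true_axes.items()},
            "landmarks": self.landmarks.tolist(),
        }


def _render_hu(spec: PhantomSpec, scene: Scene, origin, shape, spacing,
               pose: RigidTransform | None = None,
               extra_metal=None, uniform_bone_hu: float | None = None,
               include_rods: bool = True, include_fragment: bool = True,
               return_density: bool = False):
    """Supersampled (2x per axis) HU rendering of the analytic scene.

    ``pose`` moves the scene within the volume frame (points are pulled back
    through its inverse). ``extra_metal`` is a list of analytic cylinders
    (center, axis, radius, length) rendered at the saturated metal HU.
    """
    law = TRUE_HU_TO_DENSITY
    inv_pose = pose.inverse() if pose is not None else None
    nx, ny, nz = shape
    hu_acc = np.zeros(shape)
    rho_acc = np.zeros(shape) if return_density else None
    offsets = np.array([-0.25, 0.25]) * spacing
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                cx = origin[0] + np.arange(nx) * spacing + ox
                cy = origin[1] + np.arange(ny) * spacing + oy
                cz = origin[2] + np.arange(nz) * spacing + oz
                X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
                pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
                if inv_pose is not None:
                    pts = inv_pose.apply(pts)
                hu = np.full(len(pts), spec.background_hu)
                if include_rods:
                    for center, axis, radius, length, density in scene.rods():
                        m = _cylinder_contains(pts, center, axis, radius, length)
                        hu[m] = law.inverse()(density)
                bone = scene.bone_contains(pts)
                if uniform_bone_hu is not None:
                    hu[bone] = uniform_bone_hu
                    rho = None
                else:
                    rho = scene.density(pts)
                    hu[bone] = law.inverse()(rho[bone])
                if include_fragment and spec.with_fragment:
                    frag = scene.fragment_contains(pts)
                    hu[frag] = spec.metal_hu
                if extra_metal:
                    for center, axis, radius, length in extra_metal:
                        m = _cylinder_contains(pts, center, axis, radius, length)
                        hu[m] = spec.metal_hu
                hu_acc += hu.reshape(shape)
                if return_density and rho is not None:
                    rho_acc += rho.reshape(shape)
    hu_acc /= 8.0
    if return_density:
        return hu_acc, rho_acc / 8.0
    return hu_acc


def generate_phantom(spec: PhantomSpec) -> tuple[CtVolume, PhantomTruth]:
    """Render the synthetic QCT volume and its ground truth."""
    scene = Scene(spec)
    sp = spec.voxel_spacing
    if spec.volume_origin is not None or spec.volume_shape is not None:
        if spec.volume_origin is None or spec.volume_shape is None:
            raise ValueError("volume_origin and volume_shape must be given together")
        origin = np.asarray(spec.volume_origin, float)
        shape = tuple(int(n) for n in spec.volume_shape)
        lo, hi = scene.scene_bbox()
        vol_hi = origin + (np.asarray(shape) - 1) * sp
        if np.any(lo < origin) or np.any(hi > vol_hi):
            raise ValueError("phantom geometry extends outside the requested volume")
    else:
        lo, hi = scene.scene_bbox()
        # sub-voxel framing offset: scanner grids are never aligned with
        # anatomical planes, and exact alignment puts flat caps knife-edge
        # on the segmentation threshold
        origin = lo - spec.margin + 0.37 * sp
        shape = tuple(int(np.ceil((hi[a] + spec.margin - origin[a]) / sp)) + 1
                      for a in range(3))

    hu, rho = _render_hu(spec, scene, origin, shape, sp, return_density=True)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)

    volume = CtVolume(hu, spacing=sp, origin=origin)
    truth = PhantomTruth(
        spec=spec,
        scene=scene,
        true_hu_to_density=TRUE_HU_TO_DENSITY,
        true_density_field=rho,
        true_axes=scene.plan_axes(),
        rods=scene.rods(),
        landmarks=scene.landmarks(),
    )
    return volume, truth


def simulate_postdrill_volume(truth: PhantomTruth, realized_axes: dict,
                              applied_pose: RigidTransform | None = None,
                              drill_diameter: float = 2.5,
                              drill_depth: float | None = None,
                              model_hu: float = 600.0,
                              noise_sd: float | None = None,
                              seed: int = 1) -> CtVolume:
    """CT of the printed physical model with drill bits left in place.

    The physical model is a uniform solid (``model_hu``; no cortical or
    trabecular structure, no metal fragment), with one metal-HU cylinder of
    ``drill_diameter`` along each realized axis. The whole scene is moved by
    ``applied_pose`` relative to the planning frame — this is the test bench
    for the registration + axis-fit accuracy instrument.
    """
    spec = truth.spec
    scene = truth.scene
    pose = applied_pose or RigidTransform.identity()
    scale = spec.bone_shape_params.get("scale", 1.0)
    depth = drill_depth if drill_depth is not None else 40.0 * scale

    for label, axis in realized_axes.items():
        mid = axis.point + (depth / 2) * axis.direction
        if not scene.bone_contains(mid[None])[0]:
            raise ValueError(f"realized axis {label!r} does not pass through the bone")

    bits = []
    for label, axis in realized_axes.items():
        over = 10.0 * max(scale, 0.5)  # bit protrudes dorsally out of the bone
        center = axis.point + (depth - over) / 2 * axis.direction
        bits.append((tuple(center), tuple(axis.direction), drill_diameter / 2, depth + over))

    lo, hi = scene.bone_bbox()
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    allpts = [pose.apply(corners)]
    for center, axis, radius, length in bits:
        ends = np.asarray(center) + np.outer([-length / 2 - radius, length / 2 + radius],
                                             np.asarray(axis))
        allpts.append(pose.apply(ends) + [[-radius] * 3, [radius] * 3])
    allpts = np.vstack(allpts)
    sp = spec.voxel_spacing
    origin = allpts.min(axis=0) - spec.margin
    shape = tuple(int(np.ceil((allpts.max(axis=0)[a] + spec.margin - origin[a]) / sp)) + 1
                  for a in range(3))

    hu = _render_hu(spec, scene, origin, shape, sp, pose=pose, extra_metal=bits,
                    uniform_bone_hu=model_hu, include_rods=False, include_fragment=False)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, sd, size=hu.shape)
    return CtVolume(hu, spacing=sp, origin=origin)


def posed_landmarks(truth: PhantomTruth, pose: RigidTransform,
                    noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Truth landmarks as picked in the post-drill scan frame."""
    pts = pose.apply(truth.landmarks)
    if noise_sd > 0:
        pts = pts + np.random.default_rng(seed).normal(0.0, noise_sd, pts.shape)
    return pts
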