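"""Patient-specific drill-guide template generation and part comparison.

The guide is the classic navigation-template design: an offset shell that
apposes a dorsal/cranial patch of the bone surface, carrying one hollow
guide tube per planned trajectory, coaxial with the planned screw axis. The
solid is built implicitly (signed-distance composition of the shell and the
tubes, minus the bores) and triangulated with marching cubes, which makes
it watertight and printable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

import trimesh

from .meshquery import MeshQuery
from .meshutil import marching_mesh

__all__ = ["GuideSpec", "extract_contact_patch", "build_guide", "compare_cast_to_pattern"]


@dataclass
class GuideSpec:
    """Template dimensions in mm."""

    tube_inner_diameter: float = 2.7      # drill bit 2.5 + clearance
    tube_outer_diameter: float = 7.0
    tube_length: float = 22.0
    shell_thickness: float = 3.0
    standoff: float = 0.0                 # tube start offset along -axis from entry
    mc_pitch: float = 0.45

    def __post_init__(self) -> None:
        if self.shell_thickness <= 0:
            raise ValueError("shell_thickness must be positive")
        if not 0 < self.tube_inner_diameter < self.tube_outer_diameter:
            raise ValueError("need 0 < inner < outer tube diameter")
        if self.tube_length <= 0:
            raise ValueError("tube_length must be positive")


def extract_contact_patch(bone: trimesh.Trimesh, region: dict | None = None
                          ) -> trimesh.Trimesh:
    """Connected open patch of the bone surface for template contact.

    ``region`` selects faces by outward-normal direction (within
    ``max_angle_deg`` of ``normal``) and an axial window (``axis``,
    ``min_frac``..``max_frac`` of the bone's extent). Defaults pick the
    dorsal/cranial aspect (-y normals, upper half in z).
    """
    r = {"normal": (0.0, -1.0, 0.0), "max_angle_deg": 60.0,
         "axis": 2, "min_frac": 0.45, "max_frac": 0.95}
    r.update(region or {})
    n_sel = np.asarray(r["normal"], float)
    n_sel = n_sel / np.linalg.norm(n_sel)
    cosmax = np.cos(np.deg2rad(r["max_angle_deg"]))
    normals = np.asarray(bone.face_normals)
    centers = np.asarray(bone.triangles_center)
    ax = int(r["axis"])
    lo = bone.bounds[0][ax]
    hi = bone.bounds[1][ax]
    zmin = lo + r["min_frac"] * (hi - lo)
    zmax = lo + r["max_frac"] * (hi - lo)
    sel = (normals @ n_sel > cosmax) & (centers[:, ax] >= zmin) & (centers[:, ax] <= zmax)
    if not sel.any():
        raise ValueError("contact-patch selector matches no faces")
    sub = bone.submesh([np.flatnonzero(sel)], append=True)
    comps = sub.split(only_watertight=False)
    if len(comps) == 0:
        raise ValueError("contact-patch selection is empty")
    patch = max(comps, key=lambda m: m.area)
    if patch.area < 1e-6:
        raise ValueError("contact patch has vanishing area")
    return patch


def _patch_shell_sdf(points: np.ndarray, patch: trimesh.Trimesh,
                     thickness: float) -> np.ndarray:
    """Implicit solid: the patch offset outward by ``thickness``.

    For each point, with c the closest patch point, n the outward normal
    there, h the normal offset and r the tangential overshoot beyond the
    patch boundary: the slab value max(-h, h - t) is negative strictly
    between the patch and its offset, and adding r makes the solid end
    (with a rounded brim) at the patch boundary.
    """
    q = MeshQuery(patch)
    d, cp, tri = q.closest(points, k=6, return_tri=True)
    n = np.asarray(patch.face_normals)[tri]
    h = np.einsum("ij,ij->i", points - cp, n)
    r = np.linalg.norm((points - cp) - h[:, None] * n, axis=1)
    return np.maximum(-h, h - thickness) + r


def _cyl_sdf(points, base, direction, radius, length) -> np.ndarray:
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    v = points - np.asarray(base, float)
    t = v @ d
    rr = np.linalg.norm(v - np.outer(t, d), axis=1)
    dr = rr - radius
    dz = np.maximum(-t, t - length)
    outside = np.sqrt(np.maximum(dr, 0) ** 2 + np.maximum(dz, 0) ** 2)
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    return np.where((dr > 0) | (dz > 0), outside, inside)


def build_guide(patch: trimesh.Trimesh, plans, spec: GuideSpec | None = None
                ) -> trimesh.Trimesh:
    """Watertight template solid: offset shell of the patch plus one hollow
    guide tube per plan, bores cut through shell and tubes.

    Raises if a plan's axis does not pass through the patch footprint.
    """
    spec = spec or GuideSpec()
    plans = list(plans)
    pq = MeshQuery(patch)
    for plan in plans:
        d_entry, _ = pq.closest(plan.entry[None])
        if d_entry[0] > spec.shell_thickness + spec.tube_outer_diameter:
            raise ValueError(
                f"plan {plan.label!r}: axis misses the contact patch "
                f"(entry is {d_entry[0]:.1f} mm away)")

    tubes = []
    bores = []
    for plan in plans:
        start = plan.entry - spec.standoff * plan.direction
        tubes.append((start - spec.tube_length * plan.direction, plan.direction,
                      spec.tube_outer_diameter / 2, spec.tube_length + spec.shell_thickness))
        bores.append((start - (spec.tube_length + 2.0) * plan.direction, plan.direction,
                      spec.tube_inner_diameter / 2,
                      spec.tube_length + spec.shell_thickness + 6.0))

    pitch = spec.mc_pitch
    pts_ref = [patch.bounds[0], patch.bounds[1]]
    for base, d, r, L in tubes:
        ends = np.array([base, base + np.asarray(d) * L])
        pts_ref += [ends.min(axis=0) - r, ends.max(axis=0) + r]
    lo = np.min(pts_ref, axis=0) - 3 * pitch - spec.shell_thickness
    hi = np.max(pts_ref, axis=0) + 3 * pitch + spec.shell_thickness
    axes = [np.arange(lo[a], hi[a] + pitch, pitch) for a in range(3)]
    shape = tuple(len(a) for a in axes)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    f = np.full(len(pts), np.inf)
    for base, d, r, L in tubes:
        f = np.minimum(f, _cyl_sdf(pts, base, d, r, L))
    # shell only matters within a band around the patch; prune with a KD-tree
    tree = cKDTree(patch.vertices)
    d_approx, _ = tree.query(pts, k=1)
    edge = float(np.sqrt(patch.area_faces.max()))
    near = d_approx <= spec.shell_thickness + 2 * pitch + 2 * edge
    if near.any():
        f_shell = _patch_shell_sdf(pts[near], patch, spec.shell_thickness)
        f[near] = np.minimum(f[near], f_shell)
    for base, d, r, L in bores:
        f = np.maximum(f, -_cyl_sdf(pts, base, d, r, L))

    mesh = marching_mesh(f.reshape(shape), 0.0, lo, pitch)
    if not mesh.is_watertight:
        raise RuntimeError("guide solid is not watertight")
    return mesh


def compare_cast_to_pattern(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh,
                            clip_mm: float = 1.0) -> dict:
    """Part comparison: signed distance from each vertex of A to surface B.

    Negative values are inside B. Returns per-vertex distances, summary
    statistics, and a colour value per vertex clipped to [-clip, clip] mm
    for rendering (statistics are computed on the unclipped distances).
    """
    q = MeshQuery(mesh_b)
    d = q.signed_distance(np.asarray(mesh_a.vertices))
    return {
        "signed_distance_mm": d,
        "clipped": np.clip(d, -clip_mm, clip_mm),
        "mean_mm": float(d.mean()),
        "mean_abs_mm": float(np.abs(d).mean()),
        "p95_abs_mm": float(np.percentile(np.abs(d), 95)),
        "max_abs_mm": float(np.abs(d).max()),
    }
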