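"""Drilling-accuracy instrument: segment the post-drill scan, register it to
the virtual plan, fit the drill-bit axes, and report per-trajectory 3D
angles and Gertzbein-Robbins grades.

The grade follows the standard 2 mm bands of the Gertzbein-Robbins scale on
the maximal cortical breach of the (virtually implanted) screw cylinder
along the realized axis: A = no breach, B <= 2 mm, C <= 4 mm, D <= 6 mm,
E > 6 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

import trimesh

from .meshquery import MeshQuery
from .registration import landmark_register, refine_register
from .spatial import Line3D
from .screw import ScrewSpec
from .volume import CtVolume

__all__ = ["AccuracyReport", "fit_cylinder_axis", "angle_between",
           "grade_trajectory", "evaluate_drilling"]


@dataclass
class AccuracyReport:
    per_trajectory: dict                  # label -> dict with angle_deg etc.
    registration_rms_mm: float
    landmark_rms_mm: float
    details: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"registration RMS: landmark {self.landmark_rms_mm:.3f} mm, "
                 f"refined {self.registration_rms_mm:.3f} mm"]
        for label, r in sorted(self.per_trajectory.items()):
            lines.append(
                f"{label}: angle {r['angle_deg']:.2f} deg, entry offset "
                f"{r['entry_offset_mm']:.2f} mm, breach {r['breach_mm']:.2f} mm, "
                f"grade {r['grade']}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"per_trajectory": self.per_trajectory,
                "registration_rms_mm": self.registration_rms_mm,
                "landmark_rms_mm": self.landmark_rms_mm}


def fit_cylinder_axis(points: np.ndarray, expected_diameter: float | None = None,
                      cloud: str = "solid") -> Line3D:
    """Cylinder axis as the principal direction of the point cloud.

    Valid for elongated clouds (drill bits have aspect ratios ~20); raises
    if no dominant direction exists. If ``expected_diameter`` is given, the
    orthogonally refit radius is sanity-checked against it (warning when
    deviating by more than 20%). ``cloud`` says whether the points fill the
    cylinder (segmented voxels, the default) or lie on its lateral surface —
    the radius estimate differs by sqrt(2) between the two.
    """
    P = np.asarray(points, float)
    if P.ndim != 2 or len(P) < 6:
        raise ValueError("need at least 6 points")
    c = P.mean(axis=0)
    X = P - c
    cov = X.T @ X / len(P)
    w, V = np.linalg.eigh(cov)
    if w[2] < 4.0 * w[1]:
        raise ValueError("point cloud has no dominant axis (not a cylinder)")
    axis = Line3D(c, V[:, 2])
    if expected_diameter is not None:
        r = np.linalg.norm(X - np.outer(X @ axis.direction, axis.direction), axis=1)
        # for a solid (voxel-filled) cylinder the median radial distance is
        # R / sqrt(2); for surface points it is R itself
        factor = np.sqrt(2.0) if cloud == "solid" else 1.0
        fitted = 2.0 * float(np.median(r)) * factor
        if abs(fitted - expected_diameter) > 0.2 * expected_diameter:
            warnings.warn(
                f"fitted diameter {fitted:.2f} mm deviates from expected "
                f"{expected_diameter:.2f} mm by more than 20%")
    return axis


def angle_between(a: Line3D, b: Line3D) -> float:
    """Orientation-free 3D angle between two axes, in [0, 90] degrees.

    Computed via atan2(|a x b|, |a . b|), which stays accurate for nearly
    parallel axes where arccos loses precision.
    """
    cross = np.linalg.norm(np.cross(a.direction, b.direction))
    dot = abs(float(np.dot(a.direction, b.direction)))
    return float(np.degrees(np.arctan2(cross, dot)))


def grade_trajectory(realized: Line3D, screw: ScrewSpec, bone: trimesh.Trimesh,
                     corridor: trimesh.Trimesh | None = None,
                     n_axial: int = 40, n_ring: int = 24,
                     breach_floor: float = 0.3) -> tuple[str, float]:
    """Gertzbein-Robbins grade of a screw implanted along ``realized``.

    ``corridor`` is the safe-corridor solid (default: the bone itself).
    Breach is the maximum distance by which the screw cylinder surface
    protrudes outside the corridor, sampled over the inserted length.
    ``breach_floor`` is the instrument resolution: triangulated corridor
    surfaces extracted from voxel data carry chordal errors of a few tenths
    of a millimetre, so protrusions below the floor are reported but graded
    as no breach (grade A).
    """
    solid = corridor if corridor is not None else bone
    q = MeshQuery(solid)
    bq = q if corridor is None else MeshQuery(bone)
    hits = bq.ray_hits(realized.point - 200 * realized.direction, realized.direction,
                       t_min=0, t_max=400)
    if len(hits) == 0:
        raise ValueError("realized axis does not intersect the bone")
    t_entry = hits[0] - 200.0
    entry = realized.point + t_entry * realized.direction
    # the screw occupies [0, L] past the entry; exclude the oblique entry
    # funnel and (for through-going, i.e. intended bicortical, paths) the
    # planned exit region — those are not corridor breaches
    span = hits - 200.0 - t_entry
    in_span = span[(span > 1e-9) & (span <= screw.length + 1e-9)]
    t_end = float(in_span[-1]) if len(in_span) else screw.length
    margin = screw.diameter
    t_lo = min(margin, 0.4 * screw.length)
    t_hi = max(t_end - margin, t_lo + 0.1 * screw.length)
    r = screw.diameter / 2.0
    d = realized.direction
    u = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(d, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    ts = np.linspace(t_lo, min(t_hi, screw.length), n_axial)
    ang = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    ring = r * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    pts = (entry + np.outer(ts, d))[:, None, :] + ring[None, :, :]
    sd = q.signed_distance(pts.reshape(-1, 3))
    breach = float(np.maximum(sd, 0.0).max())
    if breach <= breach_floor:
        grade = "A"
    elif breach <= 2.0:
        grade = "B"
    elif breach <= 4.0:
        grade = "C"
    elif breach <= 6.0:
        grade = "D"
    else:
        grade = "E"
    return grade, breach


def segment_drill_bits(volume: CtVolume, metal_hu: float = 1500.0,
                       min_voxels: int = 30,
                       expected: int | None = None) -> list[np.ndarray]:
    """World-mm voxel-centre clouds of the metal components in the scan.

    Bits drilled through nearby entry points can nearly touch; labelling
    uses 6-connectivity, and if the component count still differs from
    ``expected`` the mask is eroded (once, then twice) to break remaining
    bridges — the eroded cores are still full-length cylinders, which is
    all the axis fit needs.
    """
    metal = volume.voxels >= metal_hu
    cx, cy, cz = volume.voxel_centers()

    def comps(mask, min_vox):
        labels, n = ndimage.label(mask)  # default structure = 6-connectivity
        out = []
        for i in range(1, n + 1):
            idx = np.argwhere(labels == i)
            if len(idx) < min_vox:
                continue
            out.append(np.stack([cx[idx[:, 0]], cy[idx[:, 1]], cz[idx[:, 2]]], axis=1))
        return out

    clouds = comps(metal, min_voxels)
    if expected is not None and len(clouds) != expected:
        work = metal
        for _ in range(2):
            work = ndimage.binary_erosion(work)
            eroded = comps(work, max(min_voxels // 4, 8))
            if len(eroded) == expected:
                return eroded
    return clouds


def evaluate_drilling(plans: dict, postdrill_volume: CtVolume,
                      plan_bone: trimesh.Trimesh, landmarks: tuple,
                      metal_hu: float = 1500.0, bone_window=(300.0, 1200.0),
                      drill_diameter: float = 2.5, refine: bool = True,
                      corridor: trimesh.Trimesh | None = None,
                      breach_floor: float | None = None) -> AccuracyReport:
    """End-to-end accuracy audit of a post-drill scan against the plan.

    ``plans`` maps label -> TrajectoryPlan (planning frame); ``landmarks``
    is a pair (points picked in the scan frame, corresponding points in the
    planning frame). The scan is segmented for metal, registered to the plan
    (landmark fit + optional ICP refinement on the bone surface), the bit
    axes fitted and matched to the plans by proximity, and each trajectory
    graded. ``breach_floor`` defaults to half the scan's voxel size — the
    surface-localization resolution of voxel-derived corridor surfaces.
    """
    from .geometry import hu_isosurface

    if breach_floor is None:
        breach_floor = 0.5 * float(np.max(postdrill_volume.spacing))

    clouds = segment_drill_bits(postdrill_volume, metal_hu, expected=len(plans))
    if len(clouds) != len(plans):
        raise ValueError(
            f"found {len(clouds)} drill bits but {len(plans)} planned trajectories")

    src_lm, dst_lm = landmarks
    tf, lm_rms = landmark_register(src_lm, dst_lm)
    icp_rms = lm_rms
    if refine:
        # greyscale isosurface: subvoxel surface localization for the ICP
        scan_bone = hu_isosurface(postdrill_volume, bone_window[0])
        tf, icp_rms = refine_register(scan_bone, plan_bone, init=tf)

    fitted = [fit_cylinder_axis(c, expected_diameter=drill_diameter).transformed(tf)
              for c in clouds]

    # match bits to plans: smallest angle + entry-distance cost, uniquely
    labels = list(plans)
    cost = np.zeros((len(fitted), len(labels)))
    for i, ax in enumerate(fitted):
        for j, lab in enumerate(labels):
            plan = plans[lab]
            cost[i, j] = (angle_between(ax, plan.axis)
                          + float(ax.distance_to_point(plan.entry)))
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(cost)
    per = {}
    for i, j in zip(rows, cols):
        plan = plans[labels[j]]
        ax = fitted[i]
        # the principal-direction fit is orientation-free; orient it along
        # the matched plan so grading walks the corridor tip-ward
        if float(np.dot(ax.direction, plan.direction)) < 0:
            ax = Line3D(ax.point, -ax.direction)
        grade, breach = grade_trajectory(ax, plan.screw, plan_bone, corridor=corridor,
                                         breach_floor=breach_floor)
        per[labels[j]] = {
            "angle_deg": angle_between(ax, plan.axis),
            "entry_offset_mm": float(ax.distance_to_point(plan.entry)),
            "breach_mm": breach,
            "grade": grade,
            "realized_point": ax.point.tolist(),
            "realized_direction": ax.direction.tolist(),
        }
    return AccuracyReport(per_trajectory=per, registration_rms_mm=float(icp_rms),
                          landmark_rms_mm=float(lm_rms),
                          details={"n_bits": len(fitted)})
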