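"""Axis fitting, angle measurement, grading, and the end-to-end audit."""

import numpy as np
import pytest
import trimesh

from sacroplan.accuracy import (angle_between, evaluate_drilling, fit_cylinder_axis,
                                grade_trajectory)
from sacroplan.screw import ScrewSpec, TrajectoryPlan
from sacroplan.spatial import Line3D, RigidTransform, rotation_about_axis


def _cylinder_surface_points(center, direction, radius, length, n=400, noise=0.0,
                             seed=0, regular=False):
    rng = np.random.default_rng(seed)
    d = np.asarray(direction, float)
    d /= np.linalg.norm(d)
    u = np.cross(d, [1.0, 0, 0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(d, [0, 1.0, 0])
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    if regular:
        # symmetric grid: cross moments vanish, so PCA is exactly the axis
        tt = np.linspace(-length / 2, length / 2, 25)
        aa = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        t = np.repeat(tt, len(aa))
        a = np.tile(aa, len(tt))
    else:
        t = rng.uniform(-length / 2, length / 2, n)
        a = rng.uniform(0, 2 * np.pi, n)
    pts = (np.asarray(center) + np.outer(t, d)
           + radius * (np.outer(np.cos(a), u) + np.outer(np.sin(a), v)))
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


class TestFitCylinderAxis:
    def test_exact_surface_points_recover_axis(self):
        d = np.array([0.3, 0.5, 0.81])
        d /= np.linalg.norm(d)
        pts = _cylinder_surface_points((1, 2, 3), d, 1.25, 50.0, regular=True)
        axis = fit_cylinder_axis(pts, expected_diameter=2.5, cloud="surface")
        assert angle_between(axis, Line3D((1, 2, 3), d)) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_points_within_half_degree(self, seed):
        d = np.array([0.2, -0.4, 0.89])
        d /= np.linalg.norm(d)
        pts = _cylinder_surface_points((0, 0, 0), d, 1.25, 50.0, noise=0.05,
                                       seed=seed)
        axis = fit_cylinder_axis(pts, cloud="surface")
        assert angle_between(axis, Line3D((0, 0, 0), d)) < 0.5

    def test_sphere_points_rejected(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(500, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        with pytest.raises(ValueError):
            fit_cylinder_axis(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cylinder_axis(np.zeros((4, 3)))


class TestAngleBetween:
    def test_parallel_lines_zero(self):
        a = Line3D((0, 0, 0), (1, 1, 0))
        b = Line3D((5, 5, 5), (1, 1, 0))
        assert angle_between(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_forty_five_degrees(self):
        a = Line3D((0, 0, 0), (1, 0, 0))
        b = Line3D((0, 0, 0), (1, 1, 0))
        assert angle_between(a, b) == pytest.approx(45.0, abs=1e-9)

    def test_orientation_free(self):
        a = Line3D((0, 0, 0), (0.3, -0.2, 0.93))
        b = Line3D((0, 0, 0), -a.direction)
        assert angle_between(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = Line3D((0, 0, 0), rng.normal(size=3))
            b = Line3D((0, 0, 0), rng.normal(size=3))
            ab, ba = angle_between(a, b), angle_between(b, a)
            assert ab == ba
            assert 0.0 <= ab <= 90.0


class TestGradeTrajectory:
    @pytest.fixture(scope="class")
    def corridor_scene(self):
        """A long block 'bone' with a cylindrical corridor just wider than
        the screw, so lateral offsets protrude by a controlled amount."""
        screw = ScrewSpec(length=40.0, diameter=6.0)
        bone = trimesh.creation.box(extents=(80, 80, 120))
        # corridor spans the full block so the screw segment after entry
        # (z in [-60, -20]) is always inside the corridor's axial range
        corridor = trimesh.creation.cylinder(radius=4.0, height=140.0, sections=128)
        return screw, bone, corridor

    def test_centred_screw_grade_a(self, corridor_scene):
        screw, bone, corridor = corridor_scene
        grade, breach = grade_trajectory(Line3D((0, 0, 0), (0, 0, 1.0)), screw,
                                         bone, corridor=corridor)
        assert grade == "A"
        assert breach == pytest.approx(0.0, abs=1e-6)

    def test_one_millimetre_protrusion_grade_b(self, corridor_scene):
        """Screw offset so the cylinder protrudes exactly 1 mm: grade B."""
        screw, bone, corridor = corridor_scene
        # corridor r=4, screw r=3: offset 2 mm -> protrusion 1 mm
        grade, breach = grade_trajectory(Line3D((2.0, 0, 0), (0, 0, 1.0)), screw,
                                         bone, corridor=corridor)
        assert breach == pytest.approx(1.0, abs=0.05)
        assert grade == "B"

    def test_seven_millimetre_protrusion_grade_e(self, corridor_scene):
        screw, bone, corridor = corridor_scene
        grade, breach = grade_trajectory(Line3D((8.0, 0, 0), (0, 0, 1.0)), screw,
                                         bone, corridor=corridor)
        assert breach == pytest.approx(7.0, abs=0.05)
        assert grade == "E"

    def test_axis_missing_bone_errors(self, corridor_scene):
        screw, bone, corridor = corridor_scene
        with pytest.raises(ValueError):
            grade_trajectory(Line3D((500.0, 0, 0), (0, 0, 1.0)), screw, bone)


class TestEvaluateDrilling:
    """End-to-end audits on the synthetic post-drill bench."""

    @pytest.fixture(scope="class")
    def bench(self, accuracy_phantom):
        spec, volume, truth = accuracy_phantom
        scale = spec.bone_shape_params["scale"]
        screw = ScrewSpec().scaled(scale)
        plans = {k: TrajectoryPlan(k, ax.point, ax.direction, screw)
                 for k, ax in truth.true_axes.items()}
        return spec, truth, plans, truth.surface("bone")

    def test_self_consistency_zero_tilt(self, bench):
        """Realized = planned, identity pose: all angles < 0.5 deg, grade A."""
        from sacroplan.phantom import simulate_postdrill_volume

        spec, truth, plans, bone = bench
        pd = simulate_postdrill_volume(truth, dict(truth.true_axes), None,
                                       noise_sd=10.0, seed=2)
        rep = evaluate_drilling(plans, pd, bone, (truth.landmarks, truth.landmarks))
        for label, r in rep.per_trajectory.items():
            assert r["angle_deg"] < 0.5
            assert r["grade"] == "A"

    def test_recovers_constructed_tilt(self, bench):
        """A 4.42 deg tilt about a known perpendicular reads back within 0.5."""
        from sacroplan.phantom import posed_landmarks, simulate_postdrill_volume

        spec, truth, plans, bone = bench
        ax = truth.true_axes["S1"]
        perp = np.cross(ax.direction, [0, 0, 1.0])
        perp /= np.linalg.norm(perp)
        realized = {"S1": Line3D(ax.point, rotation_about_axis(perp, 4.42) @ ax.direction),
                    "ALA": truth.true_axes["ALA"]}
        pose = RigidTransform.from_axis_angle([0.4, 1, 0.1], 8.0, (5, -3, 7),
                                              center=(0, 0, 10))
        pd = simulate_postdrill_volume(truth, realized, pose, noise_sd=10.0, seed=3)
        lms = (posed_landmarks(truth, pose, noise_sd=0.2, seed=4), truth.landmarks)
        rep = evaluate_drilling(plans, pd, bone, lms)
        assert rep.per_trajectory["S1"]["angle_deg"] == pytest.approx(4.42, abs=0.5)
        assert rep.per_trajectory["ALA"]["angle_deg"] < 0.5

    @pytest.mark.parametrize("seed", [0, 1])
    def test_invariant_to_rigid_scene_motion(self, bench, seed):
        """Moving the whole scene changes measured angles by < 0.2 deg."""
        from sacroplan.phantom import posed_landmarks, simulate_postdrill_volume

        spec, truth, plans, bone = bench
        ax = truth.true_axes["S1"]
        perp = np.cross(ax.direction, [0, 0, 1.0])
        perp /= np.linalg.norm(perp)
        realized = {"S1": Line3D(ax.point, rotation_about_axis(perp, 3.0) @ ax.direction),
                    "ALA": truth.true_axes["ALA"]}
        rng = np.random.default_rng(seed)
        angles = {}
        for pose in [None, RigidTransform.random(rng, 15.0, 10.0)]:
            pd = simulate_postdrill_volume(truth, realized, pose, noise_sd=5.0,
                                           seed=seed + 10)
            lm_src = posed_landmarks(truth, pose or RigidTransform.identity(),
                                     noise_sd=0.1, seed=seed + 20)
            rep = evaluate_drilling(plans, pd, bone, (lm_src, truth.landmarks))
            for k, r in rep.per_trajectory.items():
                angles.setdefault(k, []).append(r["angle_deg"])
        for k, (a0, a1) in angles.items():
            assert abs(a0 - a1) < 0.2

    def test_bit_count_mismatch_errors(self, bench):
        from sacroplan.phantom import simulate_postdrill_volume

        spec, truth, plans, bone = bench
        pd = simulate_postdrill_volume(truth, {"S1": truth.true_axes["S1"]},
                                       None, noise_sd=0.0)
        with pytest.raises(ValueError):
            evaluate_drilling(plans, pd, bone, (truth.landmarks, truth.landmarks))
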