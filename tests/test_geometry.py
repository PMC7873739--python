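"""Volume-to-surface pipeline: segmentation, extraction, smoothing, remeshing."""

import numpy as np
import pytest
import trimesh

from sacroplan.geometry import (Mask, extract_surface, remesh_uniform, segment,
                                smooth_surface)
from sacroplan.volume import CtVolume


def _edge_lengths(mesh):
    e = mesh.edges_unique
    return np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)


class TestSegment:
    def test_all_air_volume_errors(self):
        vol = CtVolume(np.full((20, 20, 20), -1000.0), 1.0)
        with pytest.raises(ValueError):
            segment(vol, 200.0)

    def test_invalid_window_rejected(self, sphere_volume):
        vol, r = sphere_volume
        with pytest.raises(ValueError):
            segment(vol, 500.0, 100.0)

    def test_sphere_voxel_count_matches_analytic(self, sphere_volume):
        vol, r = sphere_volume
        mask = segment(vol, 300.0)
        analytic = 4.0 / 3.0 * np.pi * r**3
        assert mask.volume_mm3() == pytest.approx(analytic, rel=0.02)

    def test_internal_cavity_filled(self, sphere_volume):
        """A hollow sphere segments to the same volume as the solid one."""
        vol, r = sphere_volume
        hollow = vol.voxels.copy()
        dist = np.linalg.norm(
            np.stack(np.meshgrid(*vol.voxel_centers(), indexing="ij"), -1), axis=-1)
        hollow[dist < 0.6 * r] = -100.0
        mask_solid = segment(vol, 300.0)
        mask_hollow = segment(CtVolume(hollow, vol.spacing, vol.origin), 300.0)
        assert mask_hollow.voxel_count() == pytest.approx(
            mask_solid.voxel_count(), rel=0.01)

    def test_keeps_largest_component(self, sphere_volume):
        vol, r = sphere_volume
        noisy = vol.voxels.copy()
        noisy[0:2, 0:2, 0:2] = 700.0  # small detached blob in a corner
        mask = segment(CtVolume(noisy, vol.spacing, vol.origin), 300.0)
        assert not mask.array[0, 0, 0]


class TestExtractSurface:
    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            extract_surface(Mask(np.zeros((5, 5, 5), bool), 1.0, (0, 0, 0)))

    def test_filled_cube_watertight_genus_zero(self):
        arr = np.zeros((12, 12, 12), bool)
        arr[2:10, 2:10, 2:10] = True
        mesh = extract_surface(Mask(arr, 1.0, (0, 0, 0)))
        assert mesh.is_watertight
        assert mesh.euler_number == 2  # genus 0

    def test_sphere_area_matches_analytic(self, sphere_volume):
        vol, r = sphere_volume
        mesh = extract_surface(segment(vol, 300.0))
        assert mesh.area == pytest.approx(4 * np.pi * r**2, rel=0.03)

    def test_two_blobs_two_components(self):
        arr = np.zeros((30, 12, 12), bool)
        arr[2:10, 3:9, 3:9] = True
        arr[20:28, 3:9, 3:9] = True
        mesh = extract_surface(Mask(arr, 1.0, (0, 0, 0)))
        assert mesh.body_count == 2


class TestSmoothSurface:
    def test_zero_iterations_identity(self, icosphere):
        out = smooth_surface(icosphere, 0, 0.7)
        np.testing.assert_array_equal(out.vertices, icosphere.vertices)

    def test_default_smoothing_preserves_volume(self, icosphere):
        """Six iterations at factor 0.7 change enclosed volume by <= 2%."""
        out = smooth_surface(icosphere, 6, 0.7)
        assert out.volume == pytest.approx(icosphere.volume, rel=0.02)

    def test_roughness_strictly_decreases(self):
        rng = np.random.default_rng(0)
        noisy = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        noisy.vertices += rng.normal(0, 0.15, noisy.vertices.shape)
        out = smooth_surface(noisy, 6, 0.7)
        dev_in = np.abs(np.linalg.norm(noisy.vertices, axis=1) - 10.0).max()
        dev_out = np.abs(np.linalg.norm(out.vertices, axis=1) - 10.0).max()
        assert dev_out < dev_in

    def test_parameter_validation(self, icosphere):
        with pytest.raises(ValueError):
            smooth_surface(icosphere, -1, 0.7)
        with pytest.raises(ValueError):
            smooth_surface(icosphere, 3, 1.5)


class TestRemeshUniform:
    def test_sphere_median_edge_near_target(self, icosphere):
        out = remesh_uniform(icosphere, 0.6)
        med = np.median(_edge_lengths(out))
        assert 0.45 <= med <= 0.75
        assert out.is_watertight

    def test_coarse_target_still_watertight(self, icosphere):
        out = remesh_uniform(icosphere, 50.0)
        assert out.is_watertight
        assert len(out.faces) >= 4

    def test_cube_sharp_edges_preserved(self):
        """90-degree box edges survive remeshing within 0.05 mm Hausdorff."""
        from sacroplan.meshquery import MeshQuery

        box = trimesh.creation.box(extents=(10, 10, 10))
        out = remesh_uniform(box, 1.0, sharp_angle_deg=60.0)
        assert out.is_watertight
        q = MeshQuery(out)
        ts = np.linspace(-5, 5, 51)
        pts = []
        for axis in range(3):
            for s1 in (-5, 5):
                for s2 in (-5, 5):
                    seg = np.zeros((51, 3))
                    seg[:, axis] = ts
                    seg[:, (axis + 1) % 3] = s1
                    seg[:, (axis + 2) % 3] = s2
                    pts.append(seg)
        d, _ = q.closest(np.vstack(pts))
        assert d.max() < 0.05

    def test_open_mesh_rejected(self, icosphere):
        open_mesh = icosphere.copy()
        open_mesh.faces = open_mesh.faces[:-10]
        with pytest.raises(ValueError):
            remesh_uniform(open_mesh, 1.0)

    def test_invalid_target_rejected(self, icosphere):
        with pytest.raises(ValueError):
            remesh_uniform(icosphere, 0.0)


class TestEndToEnd:
    def test_sphere_pipeline_preserves_volume(self, sphere_volume):
        """segment -> extract -> smooth -> remesh keeps volume within 3%."""
        vol, r = sphere_volume
        mesh = extract_surface(segment(vol, 300.0))
        mesh = smooth_surface(mesh, 6, 0.7)
        mesh = remesh_uniform(mesh, 1.2)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * r**3, rel=0.03)

    def test_operations_deterministic(self, sphere_volume):
        vol, r = sphere_volume
        m1 = smooth_surface(extract_surface(segment(vol, 300.0)), 3, 0.5)
        m2 = smooth_surface(extract_surface(segment(vol, 300.0)), 3, 0.5)
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
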