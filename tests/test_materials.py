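"""Calibration and density-elasticity mapping."""

import numpy as np
import pytest

from sacroplan.materials import (CalibrationSamples, DensityModulusModel, LinearLaw,
                                 SCREW_E_MPA, density_to_modulus, fit_hu_to_density,
                                 sample_rods)


class TestLinearLaw:
    def test_evaluates_exactly(self):
        law = LinearLaw(-0.0829, 0.0026)
        assert law(0.0) == -0.0829
        assert law(100.0) == pytest.approx(-0.0829 + 0.26, abs=1e-15)

    def test_inverse_round_trips(self):
        law = LinearLaw(-0.0829, 0.0026)
        x = np.linspace(-200, 1500, 7)
        np.testing.assert_allclose(law.inverse()(law(x)), x, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            LinearLaw(np.nan, 1.0)


class TestDensityToModulus:
    def test_reference_intercept_before_clamp(self):
        """At zero apparent density the raw correlation gives -34.7 MPa."""
        model = DensityModulusModel()
        raw = model.density_to_modulus(0.0)
        assert raw == pytest.approx(-34.7, abs=1e-12)

    def test_modulus_at_highest_rod_density(self):
        e, clamped = density_to_modulus(DensityModulusModel(), 0.2)
        assert e == pytest.approx(-34.7 + 3230 * 0.2, abs=1e-9)  # 611.3 MPa
        assert not clamped

    def test_clamped_below_zero_crossing(self):
        model = DensityModulusModel()
        e, clamped = density_to_modulus(model, 0.0)
        assert e == model.e_min
        assert clamped

    def test_mapping_monotone_after_clamp(self):
        model = DensityModulusModel()
        rho = np.linspace(-0.1, 2.0, 300)
        e, _ = density_to_modulus(model, rho)
        assert np.all(np.diff(e) >= 0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            DensityModulusModel(e_min=0.0)
        with pytest.raises(ValueError):
            DensityModulusModel(poisson=0.5)


class TestFitHuToDensity:
    def test_exact_line_recovered(self):
        s = CalibrationSamples([0, 50, 100, 150, 200.0],
                               [0, 0.05, 0.1, 0.15, 0.2], [99] * 5)
        law, diag = fit_hu_to_density(s)
        assert law.slope == pytest.approx(0.001, abs=1e-12)
        assert law.intercept == pytest.approx(0.0, abs=1e-12)
        assert diag["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_clinical_law_recovered_from_its_own_samples(self):
        """Samples synthesized from rho = -0.0829 + 0.0026 HU refit exactly."""
        law_true = LinearLaw(-0.0829, 0.0026)
        hu = law_true.inverse()(np.array([0, 0.05, 0.1, 0.15, 0.2]))
        s = CalibrationSamples(hu, law_true(hu), [50] * 5)
        law, _ = fit_hu_to_density(s)
        assert law.intercept == pytest.approx(-0.0829, rel=1e-10)
        assert law.slope == pytest.approx(0.0026, rel=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(4)
        hu = np.array([10.0, 60, 115, 170, 220]) + rng.normal(0, 3, 5)
        rho = np.array([0, 0.05, 0.1, 0.15, 0.2]) + rng.normal(0, 0.003, 5)
        law, _ = fit_hu_to_density(CalibrationSamples(hu, rho, [40] * 5))
        # closed-form normal equations, computed independently
        n = len(hu)
        sx, sy = hu.sum(), rho.sum()
        sxx, sxy = (hu * hu).sum(), (hu * rho).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        assert law.slope == pytest.approx(slope, rel=1e-12)
        assert law.intercept == pytest.approx(intercept, rel=1e-12)

    def test_degenerate_hu_rejected(self):
        s = CalibrationSamples([100.0, 100.0], [0.0, 0.1], [5, 5])
        with pytest.raises(ValueError):
            fit_hu_to_density(s)


class TestSampleRods:
    def test_uniform_volume_means_constant(self):
        from sacroplan.volume import CtVolume

        vol = CtVolume(np.full((40, 40, 40), 100.0), 1.0, origin=(-20, -20, -20))
        rods = [((x, 0, 0), (0, 1, 0), 5.0, 30.0, d)
                for x, d in [(-10, 0.0), (0, 0.1), (10, 0.2)]]
        s = sample_rods(vol, rods)
        np.testing.assert_allclose(s.mean_hu, 100.0)

    def test_noiseless_phantom_rods_exact(self, small_phantom_noiseless):
        """Eroded rod means reproduce the generating HU exactly (no noise)."""
        spec, volume, truth = small_phantom_noiseless
        s = sample_rods(volume, truth.rods)
        expected = truth.true_hu_to_density.inverse()(s.known_density)
        np.testing.assert_allclose(s.mean_hu, expected, atol=1e-9)

    def test_noisy_rod_means_within_clt_bound(self, small_phantom_noisy):
        spec, volume, truth = small_phantom_noisy
        s = sample_rods(volume, truth.rods)
        expected = truth.true_hu_to_density.inverse()(s.known_density)
        bound = 4.0 * spec.noise_sd / np.sqrt(s.voxel_counts)
        assert np.all(np.abs(s.mean_hu - expected) < bound)

    def test_empty_rod_interior_errors(self):
        from sacroplan.volume import CtVolume

        vol = CtVolume(np.zeros((20, 20, 20)), 1.0)
        with pytest.raises(ValueError):
            sample_rods(vol, [((10, 10, 10), (0, 0, 1), 0.5, 1.0, 0.1)])


class TestCalibrationRoundTrip:
    def test_noiseless_phantom_recovers_generating_law(self, small_phantom_noiseless):
        """Rod sampling + OLS returns the true HU->density law to 1e-10."""
        spec, volume, truth = small_phantom_noiseless
        law, _ = fit_hu_to_density(sample_rods(volume, truth.rods))
        assert law.slope == pytest.approx(truth.true_hu_to_density.slope, rel=1e-10)
        assert law.intercept == pytest.approx(truth.true_hu_to_density.intercept,
                                              rel=1e-10)


class TestAssignElementMaterials:
    @pytest.fixture(scope="class")
    def toy_mesh(self):
        import types

        import trimesh

        from sacroplan.femesh import tetrahedralize

        box = trimesh.creation.box(extents=(12, 12, 12),
                                   transform=trimesh.transformations.translation_matrix(
                                       (6, 6, 6)))
        asm = types.SimpleNamespace(bone=box, fragment=None, screws={})
        return tetrahedralize(asm, 3.0)

    def _uniform_volume(self, hu):
        from sacroplan.volume import CtVolume

        return CtVolume(np.full((40, 40, 40), float(hu)), 0.5, origin=(-2, -2, -2))

    def test_uniform_volume_gives_uniform_modulus(self, toy_mesh):
        from sacroplan.materials import assign_element_materials

        model = DensityModulusModel()
        mesh, report = assign_element_materials(toy_mesh, self._uniform_volume(400), model)
        expected = model.modulus_from_hu(400.0)
        np.testing.assert_allclose(mesh.young, expected, rtol=1e-12)
        assert (report["part"] == "bone").all()

    def test_screw_elements_get_implant_modulus(self, toy_mesh):
        from sacroplan.materials import assign_element_materials

        mesh = toy_mesh
        old = mesh.part_labels.copy()
        mesh.part_labels = old.copy()
        mesh.part_labels[:10] = "screw"
        try:
            mesh, _ = assign_element_materials(mesh, self._uniform_volume(400),
                                               DensityModulusModel())
            assert np.all(mesh.young[:10] == SCREW_E_MPA)
        finally:
            mesh.part_labels = old

    def test_two_phase_volume_bimodal(self, toy_mesh):
        """A volume split by a plane maps to exactly two modulus values."""
        from sacroplan.materials import assign_element_materials
        from sacroplan.volume import CtVolume

        hu = np.full((40, 40, 40), 200.0)
        # jump between the voxel centres at z = 5.75 and 6.25 mm, so the
        # interface coincides with the element boundary plane z = 6
        hu[:, :, 17:] = 500.0
        vol = CtVolume(hu, 0.5, origin=(-2, -2, -2.25))
        model = DensityModulusModel()
        mesh, _ = assign_element_materials(toy_mesh, vol, model)
        vals = np.unique(np.round(mesh.young, 9))
        assert len(vals) == 2
        np.testing.assert_allclose(
            sorted(vals), sorted(model.modulus_from_hu(np.array([200.0, 500.0]))))

    def test_element_outside_volume_errors(self, toy_mesh):
        from sacroplan.materials import assign_element_materials
        from sacroplan.volume import CtVolume

        small = CtVolume(np.full((5, 5, 5), 300.0), 1.0)
        with pytest.raises(ValueError):
            assign_element_materials(toy_mesh, small, DensityModulusModel())
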