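"""Generators: toy mesh, templates, surrogate fields, library, cohorts."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import impactdmn as im
from impactdmn.synthetic import (
    SurrogateParams,
    _subject_series,
    build_scenario_library,
    synth_rsfmri_cohort,
)


class TestToyHeadMesh:
    def test_contains_each_required_region(self):
        mesh = im.build_toy_head_mesh(2, 0)
        for region in ("gray", "white", "skull"):
            assert len(mesh.elements_of(region)) >= 1

    def test_deterministic_for_fixed_inputs(self):
        a = im.build_toy_head_mesh(3, 7)
        b = im.build_toy_head_mesh(3, 7)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        np.testing.assert_array_equal(a.tets, b.tets)
        np.testing.assert_array_equal(a.region_label, b.region_label)

    def test_fiber_vectors_unit_norm(self):
        mesh = im.build_toy_head_mesh(4, 7)
        white = mesh.region_label == "white"
        norms = np.linalg.norm(mesh.fiber_direction[white], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert np.all(np.isnan(mesh.fiber_direction[~white]))

    def test_positive_volumes(self, mesh):
        assert np.all(mesh.element_volume > 0)

    def test_resolution_below_two_rejected(self):
        with pytest.raises(ValueError):
            im.build_toy_head_mesh(1, 0)

    def test_vtk_roundtrip(self, tmp_path):
        mesh = im.build_toy_head_mesh(2, 0)
        path = tmp_path / "mesh.vtk"
        im.write_vtk(mesh, path)
        back = im.read_vtk(path)
        np.testing.assert_allclose(back.nodes, mesh.nodes, rtol=1e-8)
        np.testing.assert_array_equal(back.tets, mesh.tets)
        np.testing.assert_array_equal(back.region_label, mesh.region_label)


class TestDmnTemplate:
    affine = np.diag([0.01, 0.01, 0.01, 1.0])

    def test_peak_scaling(self):
        t = im.build_dmn_template((8, 8, 8), self.affine, [(0.03, 0.03, 0.03)],
                                  0.01, peak_z=6.0)
        assert t.z_map.max() == pytest.approx(6.0, abs=1e-9)

    def test_threshold_above_peak_empty(self):
        t = im.build_dmn_template((8, 8, 8), self.affine, [(0.03, 0.03, 0.03)],
                                  0.01, peak_z=3.0)
        assert not t.binarize(3.1).any()

    def test_two_disjoint_blobs_two_components(self):
        t = im.build_dmn_template((16, 16, 16), self.affine,
                                  [(0.03, 0.03, 0.03), (0.12, 0.12, 0.12)],
                                  0.008, peak_z=6.0)
        _, n = ndimage.label(t.binarize(3.1))
        assert n == 2

    def test_empty_blob_centers_rejected(self):
        with pytest.raises(ValueError):
            im.build_dmn_template((8, 8, 8), self.affine, [], 0.01, 6.0)

    def test_nifti_roundtrip(self, tmp_path, template):
        path = tmp_path / "dmn.nii.gz"
        template.to_nifti().to_filename(str(path))
        back = im.NetworkTemplate.from_nifti(path)
        np.testing.assert_allclose(back.z_map, template.z_map, rtol=1e-6)
        np.testing.assert_allclose(back.affine, template.affine, atol=1e-9)


class TestSurrogateFields:
    def test_monotone_in_velocity(self, mesh):
        params = SurrogateParams(noise_cv=0.0)
        sc1 = im.make_scenario(5.0, "vertex")
        sc2 = im.make_scenario(9.0, "vertex")
        f1 = im.surrogate_peak_fields(sc1, mesh, params)
        f2 = im.surrogate_peak_fields(sc2, mesh, params)
        assert np.all(f2.gray_peak > f1.gray_peak)

    def test_closed_form_at_reference_conditions(self, mesh):
        params = SurrogateParams(noise_cv=0.0)
        sc = im.make_scenario(params.reference_velocity, "vertex",
                              angle=0.0, impactor="round")
        assert sc.radius_of_curvature == params.reference_radius
        fields = im.surrogate_peak_fields(sc, mesh, params)
        d = np.linalg.norm(mesh.element_centroid[fields.gray_ids]
                           - sc.impact_point, axis=1)
        expected = (params.amplitude * (1.0 + params.angle_gain)
                    * np.exp(-d / params.decay_length))
        np.testing.assert_allclose(fields.gray_peak, expected, rtol=1e-12)

    def test_decreasing_with_distance(self, mesh):
        params = SurrogateParams(noise_cv=0.0)
        sc = im.make_scenario(8.0, "occipital")
        fields = im.surrogate_peak_fields(sc, mesh, params)
        d = np.linalg.norm(mesh.element_centroid[fields.gray_ids]
                           - sc.impact_point, axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(fields.gray_peak[order]) <= 0)

    def test_deterministic_per_seed(self, mesh):
        params = SurrogateParams(noise_cv=0.2, seed=9)
        sc = im.make_scenario(6.0, "temporal", 30.0, "sharp_corner")
        f1 = im.surrogate_peak_fields(sc, mesh, params)
        f2 = im.surrogate_peak_fields(sc, mesh, params)
        np.testing.assert_array_equal(f1.gray_peak, f2.gray_peak)
        np.testing.assert_array_equal(f1.skull_peak, f2.skull_peak)

    def test_velocity_out_of_range_rejected(self, mesh):
        with pytest.raises(ValueError):
            im.make_scenario(17.0, "vertex")


class TestScenarioLibrary:
    def test_record_count_is_grid_product(self, mesh, dmn_ids):
        grid = {"locations": list(im.LOCATIONS),
                "impactors": list(im.IMPACTOR_RADIUS),
                "velocities": [3.0, 5.0, 7.0, 9.0, 11.0], "angles": [0.0]}
        records = build_scenario_library(mesh, SurrogateParams(), dmn_ids,
                                         grid=grid)
        assert len(records) == 5 * 4 * 5 * 1

    def test_damage_monotone_in_velocity_within_slices(self, clean_library):
        from collections import defaultdict
        slices = defaultdict(list)
        for r in clean_library:
            key = (r.scenario.location, r.scenario.impactor, r.scenario.angle)
            slices[key].append((r.scenario.velocity, r.damage_percent))
        for rows in slices.values():
            rows.sort()
            dmg = [d for _, d in rows]
            assert np.all(np.diff(dmg) >= 0)

    def test_huge_skull_gain_fractures_everything(self, mesh, dmn_ids):
        params = SurrogateParams(skull_gain=1e6, noise_cv=0.0)
        grid = {"locations": ["vertex"], "impactors": ["flat"],
                "velocities": [4.0, 8.0], "angles": [0.0]}
        records = build_scenario_library(mesh, params, dmn_ids, grid=grid)
        assert all(r.fractured for r in records)
        assert [r for r in records if not r.fractured] == []

    def test_empty_grid_dimension_rejected(self, mesh, dmn_ids):
        grid = im.default_library_grid()
        grid["velocities"] = []
        with pytest.raises(ValueError):
            build_scenario_library(mesh, SurrogateParams(), dmn_ids, grid=grid)

    def test_default_grid_size(self):
        g = im.default_library_grid()
        n = (len(g["locations"]) * len(g["impactors"]) * len(g["velocities"])
             * len(g["angles"]))
        assert n == 420


class TestSyntheticCohort:
    def test_zero_deficit_patient_is_a_control_draw(self, template, aux_template):
        spec = im.SyntheticCohortSpec(seed=4, n_controls=2, deficit_effect=0.0)
        coh = synth_rsfmri_cohort(spec, [template, aux_template])
        # the patient's stream, generated without any deficit, must equal a
        # control generated from the same stream
        streams = np.random.SeedSequence(spec.seed).spawn(spec.n_controls + 1)
        maps = np.stack([template.z_map, aux_template.z_map])
        twin = _subject_series(np.random.default_rng(streams[-1]), maps, spec)
        np.testing.assert_array_equal(coh.patient, twin)

    def test_noiseless_single_network_is_rank_one(self, template):
        spec = im.SyntheticCohortSpec(seed=2, n_controls=2, n_networks=1,
                                      noise_sd=0.0, deficit_effect=0.0)
        coh = synth_rsfmri_cohort(spec, [template])
        series = coh.controls[0]
        # every voxel time series is s(t) scaled by the template value
        ref_vox = np.unravel_index(np.argmax(template.z_map), template.z_map.shape)
        s_t = series[ref_vox] / template.z_map[ref_vox]
        expected = template.z_map[..., None] * s_t
        np.testing.assert_allclose(series, expected, atol=1e-10)

    def test_full_deficit_zeroes_patient_beta_in_region(self, template):
        spec = im.SyntheticCohortSpec(seed=6, n_controls=2, n_networks=1,
                                      noise_sd=0.0, deficit_effect=1.0)
        coh = synth_rsfmri_cohort(spec, [template])
        beta = im.dual_regression(coh.patient, [template])[0].beta_map
        assert coh.deficit_mask.sum() > 0
        np.testing.assert_allclose(beta[coh.deficit_mask], 0.0, atol=1e-8)
        outside = template.binarize() & ~coh.deficit_mask
        assert np.all(np.abs(beta[outside]) > 1e-3)

    def test_deficit_region_is_contiguous_with_requested_size(self, template,
                                                              aux_template):
        spec = im.SyntheticCohortSpec(seed=1, deficit_fraction=0.3)
        coh = synth_rsfmri_cohort(spec, [template, aux_template])
        mask_size = int(template.binarize().sum())
        assert coh.deficit_mask.sum() == round(0.3 * mask_size)
        _, n = ndimage.label(coh.deficit_mask)
        assert n == 1

    def test_reproducible_per_seed(self, template, aux_template):
        spec = im.SyntheticCohortSpec(seed=12, n_controls=3)
        a = synth_rsfmri_cohort(spec, [template, aux_template])
        b = synth_rsfmri_cohort(spec, [template, aux_template])
        np.testing.assert_array_equal(a.patient, b.patient)
        for ca, cb in zip(a.controls, b.controls):
            np.testing.assert_array_equal(ca, cb)

    def test_too_few_timepoints_rejected(self, template, aux_template):
        spec = im.SyntheticCohortSpec(seed=0, n_timepoints=3)
        with pytest.raises(ValueError):
            synth_rsfmri_cohort(spec, [template, aux_template])
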