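"""Ray tracing, beam superposition, normalization and calibration."""

import math

import numpy as np
import pytest

import ctdose
from ctdose import dose_engine as de
from ctdose import beam_model as bm
from ctdose.errors import (CalibrationError, ConfigurationError, DomainError,
                          NormalizationError)
from conftest import uniform_box_density


def fine_step_depth(density, src, pt, step=0.01):
    """Brute-force quadrature oracle: nearest-voxel sampling at 0.01 mm."""
    src = np.asarray(src, float)
    pt = np.asarray(pt, float)
    length = np.linalg.norm(pt - src)
    n = int(length / step)
    t = (np.arange(n) + 0.5) * step / length
    pts = src[None, :] + t[:, None] * (pt - src)[None, :]
    idx = np.round((pts - np.asarray(density.origin))
                   / np.asarray(density.spacing)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(density.shape)), axis=1)
    vals = np.zeros(n)
    ii = idx[inside]
    vals[inside] = density.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return float(vals.sum() * step)


class TestRadiologicalDepth:
    def test_uniform_box_full_path(self):
        density = uniform_box_density(n=(40, 21, 21), spacing=(2.0, 2.0, 2.0))
        # ray along +x through the box center: in-box path is the box width
        lo, hi = density.bounds()
        src = (lo[0] - 50.0, 0.0, 0.0)
        pt = (hi[0] - 1.0, 0.0, 0.0)  # 1 mm inside the far face
        expected = (hi[0] - 1.0) - lo[0]
        got = de.radiological_depth(density, src, pt)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_half_vacuum_half_water(self):
        density = uniform_box_density(n=(40, 11, 11), spacing=(2.0, 2.0, 2.0))
        density.values[:20] = 0.0  # first half of the path is empty
        lo, hi = density.bounds()
        src = (lo[0] - 10.0, 0.0, 0.0)
        pt = (hi[0], 0.0, 0.0)
        assert de.radiological_depth(density, src, pt) == pytest.approx(
            (hi[0] - lo[0]) / 2.0, abs=1e-9)

    def test_random_grid_matches_fine_sampling(self, rng):
        vals = rng.uniform(0.0, 1.8, size=(30, 25, 12))
        density = ctdose.VoxelGrid(values=vals, spacing=(2.0, 2.0, 4.0),
                                   origin=(-29.0, -24.0, -22.0),
                                   value_kind="density")
        src = (200.0, 55.0, 10.0)
        for pt in [(-10.0, -8.0, 2.0), (0.0, 0.0, 0.0), (15.0, 20.0, -14.0)]:
            exact = de.radiological_depth(density, src, pt)
            approx = fine_step_depth(density, src, pt)
            assert exact == pytest.approx(approx, rel=1e-3)

    def test_source_inside_rejected(self):
        density = uniform_box_density()
        with pytest.raises(DomainError):
            de.radiological_depth(density, (0.0, 0.0, 0.0), (1.0, 1.0, 1.0))


class TestSingleBeam:
    def test_degenerate_model_gives_unit_dose(self, flat_model):
        density = uniform_box_density(n=(21, 21, 11), spacing=(2, 2, 2),
                                      value=0.0)
        spec = de.ScanSpec()
        opts = de.EngineOptions(inverse_square=False)
        dose = de.single_beam_dose(density, 0.0, 0.0, spec, flat_model, opts)
        assert np.allclose(dose.values, 1.0)

    def test_vacuum_phantom_profiles_and_inverse_square_only(self,
                                                             default_model):
        density = uniform_box_density(n=(21, 21, 5), spacing=(2, 2, 2),
                                      value=0.0)
        spec = de.ScanSpec()
        dose = de.single_beam_dose(density, 0.0, 0.0, spec, default_model)
        # independent per-voxel evaluation with numpy interpolation
        src = np.array([spec.sid, 0.0, 0.0])
        for idx in [(10, 10, 2), (4, 15, 1), (18, 3, 4)]:
            p = density.index_to_world(idx)
            v = p - src
            t = -v[0]  # central axis is -x
            xoff = v[1] * spec.sid / t  # in-plane perpendicular is +y
            zoff = v[2] * spec.sid / t
            px = np.interp(xoff, default_model.profile_x.offsets,
                           default_model.profile_x.values)
            pz = np.interp(zoff, default_model.profile_z.offsets,
                           default_model.profile_z.values)
            expected = px * pz * spec.sid**2 / np.dot(v, v)  # TMR(0) == 1
            assert dose.values[idx] == pytest.approx(expected, rel=1e-9)

    def test_central_axis_composes_verified_parts(self, default_model,
                                                  water_cylinder):
        spec = de.ScanSpec()
        dose = de.single_beam_dose(water_cylinder, 0.0, 0.0, spec,
                                   default_model)
        iso_idx = tuple(np.round(water_cylinder.world_to_index(
            (0.0, 0.0, 0.0))).astype(int))
        depth = de.radiological_depth(water_cylinder,
                                      (spec.sid, 0.0, 0.0), (0.0, 0.0, 0.0))
        expected = bm.interp_tmr(default_model.tmr, depth) \
            * np.interp(0.0, default_model.profile_x.offsets,
                        default_model.profile_x.values) \
            * np.interp(0.0, default_model.profile_z.offsets,
                        default_model.profile_z.values)
        assert dose.values[iso_idx] == pytest.approx(expected, rel=1e-9)

    def test_uncommissioned_technique_rejected(self, default_model,
                                               water_cylinder):
        spec = de.ScanSpec(bowtie="body")
        with pytest.raises(ConfigurationError):
            de.single_beam_dose(water_cylinder, 0.0, 0.0, spec, default_model)


class TestRotationalDose:
    def test_quarter_turn_symmetry_on_centered_cylinder(self, default_model):
        grid = ctdose.make_cylinder(120.0, 60.0, 0.0, spacing=(2.0, 2.0, 4.0))
        density = ctdose.hu_to_density(grid)
        spec = de.ScanSpec(n_beams=16)
        dose = de.axial_rotational_dose(density, 0.0, spec, default_model)
        rotated = np.rot90(dose.values, axes=(0, 1))
        # body voxels within the directly irradiated slice
        mask = (density.values > 0.5) \
            & (np.abs(density.axis_coords(2)) <= 8.0)[None, None, :]
        rel = np.abs(dose.values - rotated)[mask] / dose.values[mask]
        assert rel.max() < 1e-3

    def test_linear_in_profile_scale(self, default_model, water_cylinder):
        from dataclasses import replace
        spec = de.ScanSpec(n_beams=4)
        # disable the tail cutoff: linearity is a property of the raw
        # superposition formula, not of the truncation optimization
        opts = de.EngineOptions(profile_cutoff=0.0)
        base = de.axial_rotational_dose(water_cylinder, 0.0, spec,
                                        default_model, opts)
        doubled_model = replace(
            default_model,
            profile_x=replace(default_model.profile_x,
                              values=default_model.profile_x.values * 2.0))
        doubled = de.axial_rotational_dose(water_cylinder, 0.0, spec,
                                           doubled_model, opts)
        np.testing.assert_allclose(doubled.values, 2.0 * base.values,
                                   rtol=1e-12)


class TestMultisliceScan:
    def test_single_slice_reduces_to_axial_normalized(self, default_model,
                                                      water_cylinder):
        spec = de.ScanSpec(n_beams=8, slice_z_positions=(0.0,))
        multi = de.multislice_scan_dose(water_cylinder, spec, default_model)
        axial = de.axial_rotational_dose(water_cylinder, 0.0, spec,
                                         default_model)
        body = water_cylinder.values > 0.2
        np.testing.assert_allclose(multi.values,
                                   axial.values / axial.values[body].max(),
                                   rtol=1e-12)

    def test_two_slices_superpose(self, default_model, water_cylinder):
        spec = de.ScanSpec(n_beams=8, slice_z_positions=(-40.0, 40.0))
        multi = de.multislice_scan_dose(water_cylinder, spec, default_model)
        a = de.axial_rotational_dose(water_cylinder, -40.0, spec,
                                     default_model).values
        b = de.axial_rotational_dose(water_cylinder, 40.0, spec,
                                     default_model).values
        body = water_cylinder.values > 0.2
        expected = (a + b) / (a + b)[body].max()
        np.testing.assert_allclose(multi.values, expected, rtol=1e-12)

    def test_normalized_body_maximum_is_exactly_one(self, default_model,
                                                    water_cylinder):
        spec = de.ScanSpec(n_beams=8, slice_z_positions=(0.0, 10.0))
        dose = de.multislice_scan_dose(water_cylinder, spec, default_model)
        assert dose.values[water_cylinder.values > 0.2].max() == 1.0

    def test_empty_phantom_cannot_be_normalized(self, default_model):
        density = uniform_box_density(n=(9, 9, 5), spacing=(4, 4, 4),
                                      value=0.0)
        spec = de.ScanSpec(slice_z_positions=(1000.0,))
        opts = de.EngineOptions(profile_cutoff=1e-5)
        with pytest.raises(NormalizationError):
            de.multislice_scan_dose(density, spec, default_model, opts)


def boundary_distance_ellipse(a, b, e, theta):
    """Distance from interior point (e, 0) to the ellipse boundary along
    direction theta (independent quadratic-root oracle)."""
    c, s = math.cos(theta), math.sin(theta)
    A = (c / a) ** 2 + (s / b) ** 2
    B = 2 * e * c / a**2
    C = (e / a) ** 2 - 1.0
    return (-B + math.sqrt(B * B - 4 * A * C)) / (2 * A)


class TestAverageIsocenterDepth:
    def test_centered_cylinder_half_diameter(self, water_cylinder):
        d = de.average_isocenter_depth(water_cylinder, (0, 0, 0), 0.0)
        assert abs(d - 80.0) <= 0.5 * water_cylinder.spacing[0]

    def test_offset_point_in_circle_matches_quadrature(self):
        grid = ctdose.make_cylinder(160.0, 40.0, 0.0, spacing=(1.0, 1.0, 4.0))
        density = ctdose.hu_to_density(grid)
        e, R = 20.0, 80.0
        got = de.average_isocenter_depth(density, (e, 0.0, 0.0), 0.0)
        theta = np.linspace(0.0, 2 * np.pi, 360000, endpoint=False)
        expected = np.mean(np.sqrt(R**2 - (e * np.sin(theta))**2)
                           + e * np.cos(theta - np.pi))  # chord-distance law
        # the two outward-ray distance laws agree by symmetry; use the
        # direct boundary-distance form
        expected = np.mean([boundary_distance_ellipse(R, R, e, t)
                            for t in theta[::100]])
        assert got == pytest.approx(expected, rel=5e-3)

    def test_ellipse_matches_dense_brute_force(self):
        grid = ctdose.make_elliptic_cylinder(80.0, 50.0, 40.0, 0.0,
                                             spacing=(1.0, 1.0, 4.0))
        density = ctdose.hu_to_density(grid)
        e = 15.0
        got = de.average_isocenter_depth(density, (e, 0.0, 0.0), 0.0)
        theta = np.linspace(0.0, 2 * np.pi, 36000, endpoint=False)
        expected = np.mean([boundary_distance_ellipse(80.0, 50.0, e, t)
                            for t in theta])
        assert got == pytest.approx(expected, rel=5e-3)

    def test_isocenter_outside_body_rejected(self, water_cylinder):
        with pytest.raises(DomainError):
            de.average_isocenter_depth(water_cylinder, (120.0, 0.0, 0.0), 0.0)


class TestCalibration:
    def test_isocenter_anchored_to_ctdi_at_average_depth(self, default_model,
                                                         water_cylinder):
        spec = de.ScanSpec(n_beams=8)
        rel = de.multislice_scan_dose(water_cylinder, spec, default_model)
        dose, report = de.calibrate_absolute(rel, water_cylinder, spec,
                                             default_model, return_report=True)
        assert dose.point_value(spec.isocenter) == pytest.approx(
            report.ctdi_reference_mGy_100mAs, rel=1e-12)

    def test_node_depth_returns_node_value_exactly(self, default_model,
                                                   water_cylinder):
        from dataclasses import replace
        spec = de.ScanSpec(n_beams=8)
        d_avg = de.average_isocenter_depth(water_cylinder, spec.isocenter, 0.0)
        # CTDI table with a node exactly at the measured average depth
        table = bm.CTDITable(
            diameters=np.array([100.0, 2 * d_avg, 320.0]),
            center_dose=np.array([32.0, 25.0, 10.5]))
        model = replace(default_model, ctdi=table)
        rel = de.multislice_scan_dose(water_cylinder, spec, model)
        dose = de.calibrate_absolute(rel, water_cylinder, spec, model)
        assert dose.point_value(spec.isocenter) == 25.0

    def test_exactly_linear_in_mas(self, default_model, water_cylinder):
        rel = de.multislice_scan_dose(water_cylinder,
                                      de.ScanSpec(n_beams=8), default_model)
        d100 = de.calibrate_absolute(rel, water_cylinder,
                                     de.ScanSpec(n_beams=8,
                                                 mAs_per_rotation=100.0),
                                     default_model)
        d200 = de.calibrate_absolute(rel, water_cylinder,
                                     de.ScanSpec(n_beams=8,
                                                 mAs_per_rotation=200.0),
                                     default_model)
        np.testing.assert_array_equal(d200.values, 2.0 * d100.values)

    def test_off_node_depth_interpolates_bracketing_entries(self,
                                                            default_model,
                                                            water_cylinder):
        spec = de.ScanSpec(n_beams=8)
        rel = de.multislice_scan_dose(water_cylinder, spec, default_model)
        dose, report = de.calibrate_absolute(rel, water_cylinder, spec,
                                             default_model, return_report=True)
        depths = default_model.ctdi.depths
        doses = default_model.ctdi.center_dose
        d = report.average_depth_mm
        i = np.searchsorted(depths, d) - 1
        w = (d - depths[i]) / (depths[i + 1] - depths[i])
        expected = doses[i] + w * (doses[i + 1] - doses[i])
        assert dose.point_value(spec.isocenter) == pytest.approx(expected,
                                                                 rel=1e-12)

    def test_zero_relative_dose_at_isocenter_rejected(self, default_model,
                                                      water_cylinder):
        rel = de.DoseGrid(values=np.zeros(water_cylinder.shape),
                          spacing=water_cylinder.spacing,
                          origin=water_cylinder.origin, kind="relative")
        with pytest.raises(CalibrationError):
            de.calibrate_absolute(rel, water_cylinder, de.ScanSpec(),
                                  default_model)
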