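"""Commissioning-data container and interpolation behaviour."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdose import beam_model as bm
from ctdose.errors import (CommissioningError, ConfigurationError, DomainError)


def simple_tmr():
    return bm.TMRCurve(depths=np.array([0.0, 10.0, 20.0]),
                       values=np.array([1.0, 0.9, 0.8]))


class TestInterpTMR:
    @pytest.mark.parametrize("depth,expected", [(5.0, 0.95), (0.0, 1.0),
                                                (10.0, 0.9), (20.0, 0.8)])
    def test_linear_and_nodes(self, depth, expected):
        assert bm.interp_tmr(simple_tmr(), depth) == pytest.approx(expected)

    def test_exponential_tail_matches_independent_extrapolator(self):
        curve = simple_tmr()
        # independently coded closed form: continue the log-slope of the
        # final segment beyond the last node
        slope = (math.log(0.8) - math.log(0.9)) / (20.0 - 10.0)
        for depth in (21.0, 30.0, 75.0):
            expected = 0.8 * math.exp(slope * (depth - 20.0))
            assert bm.interp_tmr(curve, depth) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_negative_depth_rejected(self):
        with pytest.raises(DomainError):
            bm.interp_tmr(simple_tmr(), -1.0)

    @given(st.lists(st.floats(0.05, 1.0), min_size=3, max_size=12),
           st.integers(0, 11))
    @settings(deadline=None, max_examples=50)
    def test_exact_at_nodes_and_continuous(self, raw, pick):
        values = np.minimum.accumulate(np.sort(np.array(raw))[::-1])
        values = values / values[0]
        depths = np.linspace(0.0, 10.0 * (len(values) - 1), len(values))
        curve = bm.TMRCurve(depths=depths, values=values)
        i = pick % len(values)
        assert bm.interp_tmr(curve, depths[i]) == pytest.approx(values[i],
                                                                rel=1e-12)
        d = float(depths[-1])  # continuity at the table-to-tail transition
        eps = 1e-7
        assert bm.interp_tmr(curve, d + eps) == pytest.approx(
            bm.interp_tmr(curve, d - eps), rel=1e-4, abs=1e-6)


def triangle_profile():
    o = np.linspace(-10.0, 10.0, 21)
    v = np.clip(1.0 - np.abs(o) / 10.0, 1e-6, None)
    return bm.CrossProfile(axis="transaxial_x", offsets=o, values=v)


class TestFWHM:
    def test_symmetric_triangle_centered(self):
        c, w = bm.fwhm_center(triangle_profile())
        assert c == pytest.approx(0.0, abs=1e-12)
        assert w == pytest.approx(10.0, abs=1e-9)

    def test_rectangle(self):
        o = np.linspace(-10.0, 10.0, 201)
        v = np.where(np.abs(o) <= 5.0, 1.0, 1e-6)
        c, w = bm.fwhm_center(
            bm.CrossProfile(axis="longitudinal_z", offsets=o, values=v))
        assert c == pytest.approx(0.0, abs=0.1)
        assert w == pytest.approx(10.0, abs=0.2)

    def test_heel_trapezoid_matches_dense_scan(self):
        # asymmetric shoulders emulating the anode heel
        o = np.linspace(-15.0, 15.0, 61)
        v = np.clip(0.5 * (np.vectorize(math.erf)((o + 5.0) / 2.5)
                           - np.vectorize(math.erf)((o - 5.0) / 1.2)),
                    1e-6, None)
        prof = bm.CrossProfile(axis="longitudinal_z", offsets=o, values=v)
        c, w = bm.fwhm_center(prof)
        # brute-force oracle: dense linear interpolation, locate half-max
        # crossings by scanning
        x = np.linspace(o[0], o[-1], 300001)
        y = np.interp(x, o, v)
        half = y.max() / 2.0
        above = np.nonzero(y >= half)[0]
        left, right = x[above[0]], x[above[-1]]
        assert c == pytest.approx(0.5 * (left + right), abs=1e-3)
        assert w == pytest.approx(right - left, abs=2e-3)

    def test_never_crossing_half_maximum_is_an_error(self):
        o = np.linspace(-5.0, 5.0, 11)
        v = 0.9 + 0.1 * np.exp(-o**2)  # floor above half-max
        with pytest.raises(CommissioningError):
            bm.fwhm_center(bm.CrossProfile(axis="transaxial_x", offsets=o,
                                           values=v / v.max()))


class TestNormalizeProfile:
    def test_idempotent(self):
        once = bm.normalize_profile(triangle_profile())
        twice = bm.normalize_profile(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
        np.testing.assert_allclose(twice.offsets, once.offsets, atol=1e-12)

    def test_scale_invariant(self):
        prof = triangle_profile()
        scaled = bm.CrossProfile(axis=prof.axis, offsets=prof.offsets,
                                 values=prof.values * 3.7)
        np.testing.assert_allclose(bm.normalize_profile(scaled).values,
                                   bm.normalize_profile(prof).values,
                                   rtol=1e-12)

    def test_heel_profile_unity_at_recentred_origin(self):
        o = np.linspace(-15.0, 15.0, 121)
        v = np.clip(0.5 * (np.vectorize(math.erf)((o + 5.0) / 2.4)
                           - np.vectorize(math.erf)((o - 5.0) / 1.2)),
                    1e-6, None) * 0.63
        prof = bm.normalize_profile(
            bm.CrossProfile(axis="longitudinal_z", offsets=o, values=v))
        assert np.interp(0.0, prof.offsets, prof.values) == pytest.approx(
            1.0, abs=1e-9)


class TestCTDIReference:
    def table(self):
        return bm.CTDITable(diameters=np.array([100.0, 160.0, 240.0, 320.0]),
                            center_dose=np.array([32.0, 25.0, 16.5, 10.5]))

    def test_node_hit(self):
        assert bm.ctdi_reference(self.table(), 80.0) == 25.0

    def test_linear_midpoint(self):
        assert bm.ctdi_reference(self.table(), 65.0) == pytest.approx(28.5)

    def test_clamp_warns(self):
        with pytest.warns(bm.CTDIRangeWarning):
            assert bm.ctdi_reference(self.table(), 10.0) == 32.0

    def test_empty_table(self):
        empty = bm.CTDITable(diameters=np.array([]), center_dose=np.array([]))
        with pytest.raises(ConfigurationError):
            bm.ctdi_reference(empty, 50.0)

    @given(st.lists(st.floats(1.0, 50.0), min_size=2, max_size=6),
           st.lists(st.floats(30.0, 200.0), min_size=8, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_monotone_non_increasing_in_depth(self, doses, probes):
        dia = np.linspace(80.0, 340.0, len(doses))
        dose = np.minimum.accumulate(np.sort(np.array(doses))[::-1])
        table = bm.CTDITable(diameters=dia, center_dose=dose)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", bm.CTDIRangeWarning)
            vals = [bm.ctdi_reference(table, d) for d in sorted(probes)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestSyntheticModel:
    def test_default_satisfies_all_invariants(self):
        model = bm.generate_synthetic_beam_model(seed=0)
        bm.validate_beam_model(model)  # raises on violation

    def test_zero_heel_tilt_gives_symmetric_longitudinal_profile(self):
        model = bm.generate_synthetic_beam_model(
            bm.SyntheticBeamParams(heel_tilt=0.0), seed=0)
        v = model.profile_z.values
        o = model.profile_z.offsets
        mirrored = np.interp(-o[::-1], o, v)[::-1]
        np.testing.assert_allclose(v, mirrored, atol=1e-9)

    def test_nonzero_heel_tilt_is_asymmetric(self):
        model = bm.generate_synthetic_beam_model(seed=0)
        v = model.profile_z.values
        o = model.profile_z.offsets
        mirrored = np.interp(-o[::-1], o, v)[::-1]
        assert np.max(np.abs(v - mirrored)) > 1e-3

    def test_deterministic_for_fixed_seed(self):
        a = bm.generate_synthetic_beam_model(seed=42)
        b = bm.generate_synthetic_beam_model(seed=42)
        np.testing.assert_array_equal(a.tmr.values, b.tmr.values)
        np.testing.assert_array_equal(a.profile_x.values, b.profile_x.values)
        np.testing.assert_array_equal(a.profile_z.values, b.profile_z.values)
        np.testing.assert_array_equal(a.ctdi.center_dose, b.ctdi.center_dose)

    def test_nonphysical_params_rejected(self):
        with pytest.raises(ConfigurationError):
            bm.generate_synthetic_beam_model(
                bm.SyntheticBeamParams(mu_eff=-0.01))


class TestCSVRoundTrip:
    def test_save_load_preserves_model(self, tmp_path, default_model):
        manifest = bm.save_beam_model(default_model, tmp_path / "model")
        loaded = bm.load_beam_model(manifest)
        np.testing.assert_allclose(loaded.tmr.depths, default_model.tmr.depths)
        np.testing.assert_allclose(loaded.tmr.values, default_model.tmr.values,
                                   rtol=1e-8)
        np.testing.assert_allclose(loaded.profile_z.values,
                                   default_model.profile_z.values, rtol=1e-8)
        np.testing.assert_allclose(loaded.ctdi.center_dose,
                                   default_model.ctdi.center_dose, rtol=1e-8)
        assert loaded.bowtie == default_model.bowtie
        assert loaded.source_to_isocenter == default_model.source_to_isocenter

    def test_missing_manifest_entry_is_format_error(self, tmp_path,
                                                    default_model):
        from ctdose.errors import FormatError
        manifest = bm.save_beam_model(default_model, tmp_path / "model")
        text = manifest.read_text().replace("ctdi=ctdi.csv\n", "")
        manifest.write_text(text)
        with pytest.raises(FormatError):
            bm.load_beam_model(manifest)
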