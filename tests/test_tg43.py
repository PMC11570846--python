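"""TG-43 engine: geometry function, table interpolation, dose superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from brachyaudit.tg43 import (DwellPoint, SourceDataset, accumulate_dose,
                              dose_rate_at, geometry_function,
                              interpolate_radial)


def line_geometry_oracle(r_cm, theta_deg, L_mm):
    """Independent line-source geometry function: average of 1/d^2 over the
    active length, integrated numerically."""
    L = L_mm / 10.0
    t = np.deg2rad(theta_deg)
    px, py = r_cm * np.cos(t), r_cm * np.sin(t)

    def inv_sq(l):
        return 1.0 / ((px - l) ** 2 + py**2)

    val, _ = quad(inv_sq, -L / 2.0, L / 2.0, epsabs=1e-13, epsrel=1e-13)
    return val / L


class TestGeometryFunction:
    @pytest.mark.parametrize("r, expected", [(1.0, 1.0), (2.0, 0.25)])
    def test_point_inverse_square(self, r, expected):
        assert geometry_function(r, 90.0, model="point") == pytest.approx(expected)

    @pytest.mark.parametrize("r, theta", [(1.0, 90.0), (2.0, 45.0),
                                          (0.5, 120.0), (3.0, 10.0)])
    def test_line_matches_integration_oracle(self, r, theta):
        got = geometry_function(r, theta, active_length_mm=3.5, model="line")
        assert got == pytest.approx(line_geometry_oracle(r, theta, 3.5),
                                    rel=1e-9)

    def test_line_converges_to_point_for_short_source(self):
        for r in (1.0, 2.0, 5.0):
            g = geometry_function(r, 60.0, active_length_mm=0.01,
                                  model="line")
            assert g == pytest.approx(1.0 / r**2, rel=1e-6)

    def test_on_axis_limit_is_continuous(self):
        near = geometry_function(2.0, 1e-7, active_length_mm=3.5,
                                 model="line")
        on = geometry_function(2.0, 0.0, active_length_mm=3.5, model="line")
        assert near == pytest.approx(on, rel=1e-5)

    def test_errors(self):
        with pytest.raises(ValueError):
            geometry_function(0.0, 90.0)
        with pytest.raises(ValueError):
            geometry_function(1.0, 90.0, active_length_mm=-1.0, model="line")


class TestRadialInterpolation:
    TABLE = np.array([[1.0, 1.0], [2.0, 0.9]])

    @pytest.mark.parametrize("r, expected", [(1.0, 1.0), (1.5, 0.95)])
    def test_linear_nodes_and_midpoint(self, r, expected):
        assert interpolate_radial(self.TABLE, r) == pytest.approx(expected)

    def test_clamp_outside_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert interpolate_radial(self.TABLE, 2.3) == pytest.approx(0.9)

    def test_far_outside_is_error(self):
        with pytest.raises(ValueError):
            interpolate_radial(self.TABLE, 5.0)
        with pytest.raises(ValueError):
            interpolate_radial(np.empty((0, 2)), 1.0)


class TestDoseRate:
    def test_toy_unit_strength_reference_point(self, toy_source):
        dwell = DwellPoint((0.0, 0.0, 0.0), 0.0)
        assert dose_rate_at((10.0, 0.0, 0.0), dwell, toy_source,
                            1.0) == pytest.approx(0.01)
        assert dose_rate_at((0.0, 20.0, 0.0), dwell, toy_source,
                            1.0) == pytest.approx(0.0025)

    def test_coincident_point_is_error(self, toy_source):
        dwell = DwellPoint((0.0, 0.0, 0.0), 1.0)
        with pytest.raises(ValueError):
            dose_rate_at((0.0, 0.0, 0.0), dwell, toy_source, 1.0)

    def test_line_equals_point_at_reference_point(self, toy_source):
        """With all tables == 1 the geometry ratio G/G0 cancels at
        (r0, theta0), so line and point models agree there exactly."""
        line = SourceDataset(
            label="toy line", radionuclide="toy", dose_rate_constant=1.0,
            active_length_mm=3.5, geometry_model="line",
            radial_dose=toy_source.radial_dose,
            anisotropy_r=toy_source.anisotropy_r,
            anisotropy_theta=toy_source.anisotropy_theta,
            anisotropy_F=toy_source.anisotropy_F)
        dwell = DwellPoint((0.0, 0.0, 0.0), 0.0)
        point_mm = (0.0, 10.0, 0.0)   # r = 1 cm, theta = 90 deg
        assert dose_rate_at(point_mm, dwell, line, 1.0) == pytest.approx(
            dose_rate_at(point_mm, dwell, toy_source, 1.0), rel=1e-12)

    @given(r_mm=st.floats(5.0, 80.0))
    @settings(max_examples=30, deadline=None)
    def test_inverse_square_property(self, toy_source, r_mm):
        dwell = DwellPoint((0.0, 0.0, 0.0), 0.0)
        near = dose_rate_at((r_mm, 0.0, 0.0), dwell, toy_source, 1.0)
        far = dose_rate_at((2 * r_mm, 0.0, 0.0), dwell, toy_source, 1.0)
        assert far / near == pytest.approx(0.25, rel=1e-12)


class TestAccumulateDose:
    def test_zero_time_gives_zero_dose(self, toy_source):
        dwells = [DwellPoint((0.0, 0.0, 0.0), 0.0)]
        doses = accumulate_dose([(10.0, 0.0, 0.0)], dwells, toy_source, 1.0)
        assert doses[0] == 0.0

    def test_rate_times_time(self, toy_source):
        dwells = [DwellPoint((0.0, 0.0, 0.0), 3600.0)]
        doses = accumulate_dose([(10.0, 0.0, 0.0)], dwells, toy_source, 1.0)
        assert doses[0] == pytest.approx(0.01)

    def test_dwell_time_splitting_is_additive(self, toy_source):
        one = [DwellPoint((5.0, 0.0, 0.0), 3600.0)]
        split = [DwellPoint((5.0, 0.0, 0.0), 1800.0),
                 DwellPoint((5.0, 0.0, 0.0), 1800.0)]
        pts = [(30.0, 10.0, 0.0)]
        assert accumulate_dose(pts, one, toy_source, 1.0) == pytest.approx(
            accumulate_dose(pts, split, toy_source, 1.0))

    def test_three_dwell_hand_summed_oracle(self, toy_source):
        """Independent inverse-square hand sum over three toy dwells."""
        dwells = [DwellPoint((0.0, 0.0, 0.0), 3600.0),
                  DwellPoint((10.0, 0.0, 0.0), 7200.0),
                  DwellPoint((0.0, 20.0, 0.0), 3600.0)]
        point = (0.0, 10.0, 0.0)
        # distances (cm): 1, sqrt(2), 1; rate = 0.01/r^2 Gy/h
        expected = 0.01 * (1.0 / 1.0 * 1.0
                           + 1.0 / 2.0 * 2.0
                           + 1.0 / 1.0 * 1.0)
        got = accumulate_dose([point], dwells, toy_source, 1.0)[0]
        assert got == pytest.approx(expected, rel=1e-12)


class TestSourceDataset:
    def test_invariant_violations_rejected(self, toy_source):
        with pytest.raises(ValueError, match="g\\(1 cm\\)"):
            SourceDataset(
                label="bad", radionuclide="toy", dose_rate_constant=1.0,
                active_length_mm=0.0, geometry_model="point",
                radial_dose=[[0.5, 1.1], [2.0, 1.2]],
                anisotropy_r=toy_source.anisotropy_r,
                anisotropy_theta=toy_source.anisotropy_theta,
                anisotropy_F=toy_source.anisotropy_F)
        with pytest.raises(ValueError, match="F\\(r, 90"):
            SourceDataset(
                label="bad", radionuclide="toy", dose_rate_constant=1.0,
                active_length_mm=0.0, geometry_model="point",
                radial_dose=toy_source.radial_dose,
                anisotropy_r=[1.0], anisotropy_theta=[0.0, 90.0, 180.0],
                anisotropy_F=[[0.9, 0.95, 0.9]])

    def test_bundled_tables_satisfy_invariants(self, ir_source, co_source):
        for src in (ir_source, co_source):
            assert src.radial_dose_function(1.0) == pytest.approx(1.0)
            assert src.anisotropy(2.0, 90.0) == pytest.approx(1.0)
            assert src.geometry_model == "line"
            # anisotropy symmetric enough about 90 deg and below 1 off-axis
            assert src.anisotropy(2.0, 20.0) < 1.0

    def test_json_round_trip(self, ir_source, tmp_path):
        path = tmp_path / "src.json"
        ir_source.to_json(path)
        back = SourceDataset.from_json(path)
        np.testing.assert_allclose(back.radial_dose, ir_source.radial_dose)
        np.testing.assert_allclose(back.anisotropy_F, ir_source.anisotropy_F)
        assert back.label == ir_source.label
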