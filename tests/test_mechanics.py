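"""Reduced-order motion-segment mechanics."""

import math

import numpy as np
import pytest

from vertegrow import (
    HIGH_TENSION,
    LOW_TENSION,
    MotionSegment,
    TetherConstruct,
    calibrate_defaults,
    equilibrium_angle,
    pressure_load_curve,
    realign,
    resolve_axis,
)
from vertegrow.mechanics import ContactError, _internal_moment


@pytest.fixture
def segment():
    return MotionSegment()


class TestKinematics:
    def test_flexible_axis_preserves_middisc_height(self, segment):
        state = realign(segment, 10.0, "flexible")
        assert abs(state.height_change_at(segment.radius_r)) < 1e-12

    def test_stiff_axis_preserves_anterior_edge(self, segment):
        state = realign(segment, 10.0, "stiff")
        assert abs(state.height_change_at(0.0)) < 1e-12

    def test_center_rotation_edge_heights_match_trigonometry(self, segment):
        state = realign(segment, 10.0, "flexible")
        oracle = segment.radius_r * math.tan(math.radians(10.0))
        assert state.height_change_at(0.0) == pytest.approx(oracle, abs=1e-12)
        assert state.height_change_at(segment.width) == pytest.approx(
            -oracle, abs=1e-12
        )

    def test_height_field_is_affine_in_x(self, segment):
        state = realign(segment, 7.0, "flexible")
        slopes = np.diff(state.dh) / np.diff(state.positions)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)

    def test_contact_raises(self, segment):
        with pytest.raises(ContactError, match="closes"):
            realign(segment, 30.0, "stiff")

    def test_axis_resolution(self, segment):
        assert resolve_axis(segment, "flexible") == segment.radius_r
        assert resolve_axis(segment, "stiff") == 0.0
        assert resolve_axis(segment, 12.0) == 12.0
        with pytest.raises(ValueError, match="unknown axis"):
            resolve_axis(segment, "rigid")
        with pytest.raises(ValueError, match="footprint"):
            resolve_axis(segment, 31.0)


class TestStressField:
    def test_neutral_state_is_homeostatic_everywhere(self, segment):
        state = realign(segment, 0.0, "flexible")
        np.testing.assert_allclose(
            state.sigma_gp, -segment.swelling_pressure_p0, atol=1e-14
        )
        assert state.p_np == pytest.approx(segment.swelling_pressure_p0)

    def test_flexible_correction_signs(self, segment):
        state = realign(segment, 10.0, "flexible")
        u = state.positions / segment.width
        annulus_ant = state.sigma_gp[u < 0.25]
        annulus_post = state.sigma_gp[u >= 0.75]
        assert np.all(annulus_ant > -segment.swelling_pressure_p0)
        assert np.all(annulus_post < -segment.swelling_pressure_p0)

    def test_np_pressure_matches_bruteforce_volume_integral(self, segment):
        theta = 10.0
        for axis in ("flexible", "stiff"):
            state = realign(segment, theta, axis)
            lo = 0.25 * segment.width + segment.np_centroid_offset_delta
            hi = 0.75 * segment.width + segment.np_centroid_offset_delta
            grid = np.linspace(lo, hi, 200_001)
            dh = state.height_change_at(grid[0]) + (
                grid - grid[0]
            ) * (state.height_change_at(hi) - state.height_change_at(lo)) / (
                hi - lo
            )
            vol_out = -np.trapezoid(dh, grid)
            v0 = segment.disc_height_h0 * (hi - lo)
            expected = max(
                0.0,
                segment.swelling_pressure_p0
                + (vol_out / v0) / segment.np_compliance_C,
            )
            assert state.p_np == pytest.approx(expected, abs=1e-10)


class TestCalibration:
    def test_solver_reproduces_shipped_constants(self, segment):
        result = calibrate_defaults()
        assert result.C == pytest.approx(segment.np_compliance_C, abs=1e-9)
        assert result.delta == pytest.approx(
            segment.np_centroid_offset_delta, abs=1e-9
        )
        assert max(abs(r) for r in result.residuals) < 1e-10

    def test_nonfinite_targets_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            calibrate_defaults((float("nan"), -0.005, 0.297))


class TestEquilibrium:
    def test_force_angle_round_trip(self, segment):
        for F in (5.0, 25.6):
            theta, state = equilibrium_angle(segment, HIGH_TENSION, F)
            lever = segment.radius_r + HIGH_TENSION.moment_arm_d - state.x_rot
            recovered = _internal_moment(
                segment, math.tan(math.radians(theta)), state.x_rot
            ) / (HIGH_TENSION.n_cables * lever)
            assert recovered == pytest.approx(F, rel=1e-9)

    def test_zero_force_means_zero_correction(self, segment):
        theta, state = equilibrium_angle(segment, LOW_TENSION, 0.0)
        assert theta == 0.0 and state.p_np == pytest.approx(0.15)

    def test_angle_increases_with_force(self, segment):
        thetas = [
            equilibrium_angle(segment, LOW_TENSION, F)[0]
            for F in (2.0, 5.0, 10.0, 25.6)
        ]
        assert all(b > a for a, b in zip(thetas, thetas[1:]))

    def test_negative_force_rejected(self, segment):
        with pytest.raises(ValueError, match="non-negative"):
            equilibrium_angle(segment, LOW_TENSION, -1.0)


class TestLoadCurve:
    def test_monotone_correction_and_pressure(self, segment):
        construct = TetherConstruct(pretension=5.0)
        df = pressure_load_curve(segment, construct, np.linspace(0, 30, 11))
        assert df["theta_eq_deg"].is_monotonic_increasing
        assert df["apical_angle_deg"].is_monotonic_decreasing
        # flexible-regime NP pressure never increases with load
        assert np.all(np.diff(df["p_np_kpa"]) <= 1e-9)

    def test_grid_validation(self, segment):
        construct = TetherConstruct()
        with pytest.raises(ValueError, match="non-negative"):
            pressure_load_curve(segment, construct, [-1.0, 2.0])
        with pytest.raises(ValueError, match="increasing"):
            pressure_load_curve(segment, construct, [2.0, 1.0])


class TestConstructValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError, match="pretension"):
            TetherConstruct(pretension=-1.0)
        with pytest.raises(ValueError, match="moment arm"):
            TetherConstruct(moment_arm_d=0.0)
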