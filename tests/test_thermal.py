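import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitotherm.bioenergetics import ThermogenicDrive
from mitotherm.thermal import (
    DriveSegment,
    MitochondrionSpec,
    TemperatureTrace,
    ThermalEnvironment,
    capacity_utilization,
    classify_state,
    heating_rate,
    integrate_temperature,
    surface_gradient,
)


class TestGeometry:
    def test_sphere_radius_from_unit_volume(self, unit_mito):
        assert unit_mito.radius_um == pytest.approx(0.6204, rel=1e-3)
        # area and volume consistent with the derived radius
        r = unit_mito.radius_um
        assert unit_mito.surface_area_um2 == pytest.approx(4 * math.pi * r**2, rel=1e-9)
        assert 4 / 3 * math.pi * r**3 == pytest.approx(unit_mito.volume_um3, rel=1e-9)

    def test_environment_diffusivity_derived(self, water_env):
        assert water_env.diffusivity_m2_per_s == pytest.approx(
            0.6 / 4.18e6, rel=1e-12
        )

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            MitochondrionSpec(0.0)


class TestHeatingRate:
    def test_canonical_rate_near_4_8(self, canonical_drive, unit_mito, water_env):
        rate = heating_rate(canonical_drive, unit_mito, water_env)
        assert rate == pytest.approx(4.8, rel=0.05)
        assert rate == pytest.approx(2e-11 / 4.18e-12, rel=1e-12)

    def test_zero_efficiency_erythrocyte(self, unit_mito, water_env):
        drive = ThermogenicDrive(100.0, 200.0, efficiency=0.0)
        assert heating_rate(drive, unit_mito, water_env) == 0.0

    def test_typical_cell_efficiency(self, unit_mito, water_env):
        drive = ThermogenicDrive(100.0, 200.0, efficiency=0.6)
        assert heating_rate(drive, unit_mito, water_env) == pytest.approx(2.87, rel=5e-3)

    @settings(derandomize=True, max_examples=50)
    @given(
        eta=st.floats(0.01, 1.0),
        current=st.floats(1.0, 500.0),
        pmf=st.floats(50.0, 250.0),
        volume=st.floats(0.2, 5.0),
        scale=st.floats(0.5, 2.0),
    )
    def test_linearity_in_each_factor(self, eta, current, pmf, volume, scale):
        spec = MitochondrionSpec(volume)
        env = ThermalEnvironment()
        base = heating_rate(ThermogenicDrive(current, pmf, efficiency=eta), spec, env)
        assert heating_rate(
            ThermogenicDrive(current * scale, pmf, efficiency=eta), spec, env
        ) == pytest.approx(base * scale, rel=1e-9)
        assert heating_rate(
            ThermogenicDrive(current, pmf * scale, efficiency=eta), spec, env
        ) == pytest.approx(base * scale, rel=1e-9)
        assert heating_rate(
            ThermogenicDrive(current, pmf, efficiency=eta), MitochondrionSpec(volume * scale), env
        ) == pytest.approx(base / scale, rel=1e-9)
        bigger_C = ThermalEnvironment(0.6, 4.18e6 * scale)
        assert heating_rate(
            ThermogenicDrive(current, pmf, efficiency=eta), spec, bigger_C
        ) == pytest.approx(base / scale, rel=1e-9)


class TestSurfaceGradient:
    def test_canonical_magnitude(self, canonical_drive, unit_mito, water_env):
        mag, direction = surface_gradient(canonical_drive, unit_mito, water_env)
        assert mag == pytest.approx(6.9, rel=0.01)
        assert "inward" in direction

    def test_zero_current_steady_state(self, unit_mito, water_env):
        mag, _ = surface_gradient(ThermogenicDrive(0.0, 200.0), unit_mito, water_env)
        assert mag == 0.0

    def test_inverse_square_in_radius(self, canonical_drive, water_env):
        small = MitochondrionSpec(1.0)
        big = MitochondrionSpec(8.0)  # doubles the radius
        m_small, _ = surface_gradient(canonical_drive, small, water_env)
        m_big, _ = surface_gradient(canonical_drive, big, water_env)
        assert m_big == pytest.approx(m_small / 4.0, rel=1e-9)

    def test_gradient_inverts_to_power(self, canonical_drive, unit_mito, water_env):
        mag, _ = surface_gradient(canonical_drive, unit_mito, water_env)
        recovered = mag * 4 * math.pi * water_env.conductivity_W_per_mK * unit_mito.radius_m**2
        assert recovered == pytest.approx(canonical_drive.power_W, rel=1e-12)


class TestStateClassification:
    def test_resting_state_is_steady(self):
        assert classify_state(ThermogenicDrive(0.0, 200.0)) == "steady"

    def test_active_ucp1_is_thermogenic(self):
        assert classify_state(ThermogenicDrive(100.0, 200.0)) == "thermogenic"

    def test_subtolerance_current_counts_as_steady(self):
        assert classify_state(ThermogenicDrive(1e-30, 200.0)) == "steady"

    @settings(derandomize=True, max_examples=50)
    @given(current=st.floats(0, 500))
    def test_steady_iff_zero_heating_rate(self, current):
        spec, env = MitochondrionSpec(), ThermalEnvironment()
        drive = ThermogenicDrive(current, 200.0)
        rate = heating_rate(drive, spec, env)
        rate_tol = heating_rate(ThermogenicDrive(1e-6, 200.0), spec, env)
        steady = classify_state(drive) == "steady"
        assert steady == (abs(rate) < rate_tol)


class TestIntegrateTemperature:
    def test_constant_drive_matches_closed_form(self, unit_mito, water_env):
        trace = integrate_temperature(
            [DriveSegment(0.0, 100.0, 1.0)], 200.0, unit_mito, water_env,
            T0_K=310.0, t_end_s=0.1, dt_s=0.01,
        )
        rate = 2e-11 / 4.18e-12
        assert trace.values_K[-1] == pytest.approx(310.0 + rate * 0.1, abs=1e-12)
        np.testing.assert_allclose(trace.values_K, 310.0 + rate * trace.times_s)

    def test_zero_drive_is_flat(self, unit_mito, water_env):
        trace = integrate_temperature(
            [DriveSegment(0.0, 0.0)], 200.0, unit_mito, water_env, 310.0, 10.0, 1.0
        )
        np.testing.assert_array_equal(trace.values_K, np.full(11, 310.0))

    def test_two_segment_heat_then_plateau(self, water_env):
        # current chosen so the first-segment rate is 0.06 K/s
        spec = MitochondrionSpec(1.0)
        I = 0.06 * 4.18e-12 / 0.2 * 1e12
        trace = integrate_temperature(
            [DriveSegment(0.0, I), DriveSegment(60.0, 0.0)],
            200.0, spec, water_env, 310.0, 120.0, 1.0,
        )
        i60 = np.searchsorted(trace.times_s, 60.0)
        assert trace.values_K[i60] == pytest.approx(313.6, abs=1e-9)
        assert trace.values_K[-1] == pytest.approx(313.6, abs=1e-9)

    def test_schedule_gap_rejected(self, unit_mito, water_env):
        with pytest.raises(ValueError, match="gap"):
            integrate_temperature(
                [DriveSegment(5.0, 100.0)], 200.0, unit_mito, water_env, 310.0, 10.0, 1.0
            )


class TestCapacityUtilization:
    def test_sustained_average_is_a_tenth_of_a_percent(self):
        assert capacity_utilization(0.005, 4.785) == pytest.approx(0.10, rel=0.05)

    def test_experimental_max_is_about_one_percent(self):
        assert capacity_utilization(0.06, 4.785) == pytest.approx(1.25, rel=0.01)

    def test_zero_observed(self):
        assert capacity_utilization(0.0, 4.785) == 0.0

    def test_rejects_nonpositive_theoretical(self):
        with pytest.raises(ValueError):
            capacity_utilization(0.06, 0.0)


class TestTemperatureTrace:
    def test_rejects_decreasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            TemperatureTrace(np.array([0.0, 2.0, 1.0]), np.array([310.0] * 3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            TemperatureTrace(np.array([0.0, 1.0]), np.array([310.0]))
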