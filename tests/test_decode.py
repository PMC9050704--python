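import numpy as np
import pytest

from scmotormap.decode import (SaccadeTrajectory, decode_trajectory,
                               eye_velocity, fit_kinematic_slope,
                               fit_main_sequence, saccade_metrics,
                               spike_density, central_cell)
from scmotormap.geometry import MapGrid, MotorMap
from scmotormap.network import SpikeRecord

MAP = MotorMap(MapGrid())
ZETA, N_REF = 1.0, 500.0


def make_record(times_by_neuron, t_end=400.0):
    times = [np.sort(np.asarray(times_by_neuron.get(n, []), dtype=float))
             for n in range(200)]
    return SpikeRecord("sc", times, MAP.grid.positions, 0.05, t_end)


class TestDecodeTrajectory:
    def test_single_spike_is_step_of_height_m(self):
        rec = make_record({100: [50.0]})
        traj = decode_trajectory(rec, MAP, ZETA, N_REF)
        m = MAP.spike_vectors(ZETA, N_REF)[100]
        assert traj.S_deg[0] == 0.0
        assert traj.S_deg[-1] == pytest.approx(m, abs=1e-15)
        assert np.all(np.diff(traj.S_deg) >= 0)

    def test_amplitude_conservation(self):
        rng = np.random.default_rng(7)
        spikes = {n: rng.uniform(0, 390, rng.integers(0, 25))
                  for n in range(80, 130)}
        rec = make_record(spikes)
        traj = decode_trajectory(rec, MAP, 1.3, N_REF)
        m = MAP.spike_vectors(1.3, N_REF)
        expected = sum(m[n] * len(t) for n, t in spikes.items())
        assert traj.S_deg[-1] == pytest.approx(expected, abs=1e-9)

    def test_concatenation_additivity(self):
        a = make_record({90: [10.0, 20.0]})
        b = make_record({110: [30.0, 200.0]})
        both = make_record({90: [10.0, 20.0], 110: [30.0, 200.0]})
        Sa = decode_trajectory(a, MAP, ZETA, N_REF).S_deg
        Sb = decode_trajectory(b, MAP, ZETA, N_REF).S_deg
        Sab = decode_trajectory(both, MAP, ZETA, N_REF).S_deg
        assert np.allclose(Sab, Sa + Sb, atol=1e-12)

    def test_empty_record_decodes_to_zero(self):
        traj = decode_trajectory(make_record({}), MAP, ZETA, N_REF)
        assert np.all(traj.S_deg == 0.0)

    def test_wrong_layer_rejected(self):
        rec = make_record({100: [50.0]})
        rec.layer = "input"
        with pytest.raises(ValueError):
            decode_trajectory(rec, MAP, ZETA, N_REF)

    def test_time_rescaling_preserves_amplitude(self):
        rng = np.random.default_rng(3)
        spikes = {n: rng.uniform(10, 80, 12) for n in range(95, 106)}
        rec = make_record(spikes)
        stretched = make_record({n: 2.0 * t for n, t in spikes.items()})
        S1 = decode_trajectory(rec, MAP, ZETA, N_REF).S_deg
        S2 = decode_trajectory(stretched, MAP, ZETA, N_REF).S_deg
        assert S1[-1] == pytest.approx(S2[-1], abs=1e-9)


class TestEyeVelocity:
    def test_constant_position_zero_velocity(self):
        t = np.arange(0, 200.0, 1.0)
        traj = eye_velocity(SaccadeTrajectory(t, np.full_like(t, 3.0)))
        assert np.allclose(traj.V_deg_s, 0.0, atol=1e-9)

    def test_ramp_reproduced_exactly_in_interior(self):
        t = np.arange(0, 200.0, 1.0)
        slope = 0.25  # deg/ms = 250 deg/s
        traj = eye_velocity(SaccadeTrajectory(t, slope * t), window=21, order=3)
        assert np.allclose(traj.V_deg_s[10:-10], 250.0, atol=1e-9)

    @pytest.mark.parametrize("window, order", [(20, 3), (1, 0), (5, 7)])
    def test_filter_validation(self, window, order):
        t = np.arange(0, 100.0, 1.0)
        with pytest.raises(ValueError):
            eye_velocity(SaccadeTrajectory(t, t), window=window, order=order)

    def test_short_trace_rejected(self):
        t = np.arange(0, 10.0, 1.0)
        with pytest.raises(ValueError):
            eye_velocity(SaccadeTrajectory(t, t), window=21, order=3)


def triangle_trajectory(R=12.0, D=60.0, dt=1.0, t_end=200.0, onset=40.0):
    """Closed-form saccade with a triangular velocity profile."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    vp = 2.0 * R / D  # deg/ms
    v = np.zeros_like(t)
    rising = (t >= onset) & (t < onset + D / 2)
    falling = (t >= onset + D / 2) & (t <= onset + D)
    v[rising] = vp * 2.0 * (t[rising] - onset) / D
    v[falling] = vp * 2.0 * (onset + D - t[falling]) / D
    S = np.cumsum(v) * dt
    return SaccadeTrajectory(t, S)


class TestSaccadeMetrics:
    def test_zero_trajectory_flagged(self):
        t = np.arange(0, 100.0, 1.0)
        m = saccade_metrics(SaccadeTrajectory(t, np.zeros_like(t)))
        assert not m.valid and m.amplitude_deg == 0.0

    def test_triangular_profile_k_near_2(self):
        # exact triangle geometry gives Vp*D/R = 2; the 5%-of-peak crossings
        # shave 5% off D (-> 1.9) and the filter rounds the velocity apex a
        # little further
        m = saccade_metrics(eye_velocity(triangle_trajectory(), window=5, order=2))
        k = m.peak_velocity_deg_s * (m.duration_ms / 1000.0) / m.amplitude_deg
        assert k == pytest.approx(1.9, abs=0.1)

    def test_gaussian_velocity_pulse_amplitude_recovered(self):
        t = np.arange(0.0, 300.0, 1.0)
        R, sigma, t0 = 17.0, 12.0, 120.0
        v = R / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        S = np.cumsum(v) * 1.0
        m = saccade_metrics(eye_velocity(SaccadeTrajectory(t, S), window=11, order=3))
        assert m.amplitude_deg == pytest.approx(R, rel=0.02)
        assert m.onset_ms < t0 < m.offset_ms


class TestSpikeDensity:
    def test_empty_train_zero_trace(self):
        grid, dens = spike_density(np.array([]))
        assert np.all(dens == 0.0)

    def test_single_spike_unit_area(self):
        grid, dens = spike_density(np.array([50.0]), kernel_sigma_ms=4.0, dt_ms=0.2)
        area = np.trapezoid(dens, grid) / 1000.0
        assert area == pytest.approx(1.0, rel=1e-3)

    def test_integral_equals_spike_count(self):
        rng = np.random.default_rng(11)
        times = np.sort(rng.uniform(20, 200, 37))
        grid, dens = spike_density(times, kernel_sigma_ms=4.0, dt_ms=0.2)
        area = np.trapezoid(dens, grid) / 1000.0
        assert area == pytest.approx(37.0, rel=1e-3)

    def test_periodic_train_plateau(self):
        rate = 0.2  # per ms = 200 spk/s
        times = np.arange(0.0, 500.0, 1.0 / rate)
        grid, dens = spike_density(times, kernel_sigma_ms=20.0, dt_ms=0.5)
        mid = (grid > 150) & (grid < 350)
        assert np.mean(dens[mid]) == pytest.approx(200.0, rel=0.02)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            spike_density(np.array([1.0]), kernel_sigma_ms=0.0)


class TestCentralCell:
    def test_max_count_wins(self):
        rec = make_record({90: [1, 2, 3], 120: [1, 2]})
        assert central_cell(rec, 2.5) == 90

    def test_tie_breaks_toward_image_point(self):
        rec = make_record({90: [1, 2], 110: [1, 2]})
        # both 10 neurons from u_T = 2.5 -> nearest wins; make asymmetric
        rec2 = make_record({80: [1, 2], 101: [1, 2]})
        assert central_cell(rec2, 2.5) == 101


class TestFits:
    def test_main_sequence_noise_free_recovery(self):
        R = np.array([2, 5, 8, 11, 15, 19, 24, 30, 37, 45], dtype=float)
        V0, alpha = 1637.0, 0.031
        V = V0 * (1 - np.exp(-alpha * R))
        fit = fit_main_sequence(R, V)
        assert fit.V0_deg_s == pytest.approx(V0, rel=1e-4)
        assert fit.alpha_per_deg == pytest.approx(alpha, rel=1e-4)

    def test_main_sequence_recovery_under_5pct_noise(self):
        rng = np.random.default_rng(42)
        R = np.linspace(2, 45, 25)
        V = 1637.0 * (1 - np.exp(-0.031 * R)) * (1 + 0.05 * rng.standard_normal(25))
        fit = fit_main_sequence(R, V)
        assert fit.V0_deg_s == pytest.approx(1637.0, rel=0.10)
        assert fit.alpha_per_deg == pytest.approx(0.031, rel=0.10)

    def test_near_linear_data_slope_is_V0_alpha(self):
        R = np.linspace(0.5, 3.0, 10)
        slope = 40.0
        fit = fit_main_sequence(R, slope * R)
        assert fit.V0_deg_s * fit.alpha_per_deg == pytest.approx(slope, rel=0.02)

    def test_kinematic_slope_exact(self):
        R = np.array([3.0, 10.0, 25.0])
        fit = fit_kinematic_slope(R, 2.0 * R)
        assert fit.k == pytest.approx(2.0, abs=1e-12)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_fit_validation(self):
        with pytest.raises(ValueError):
            fit_main_sequence([1.0, 2.0], [10.0, 20.0])
        with pytest.raises(ValueError):
            fit_kinematic_slope([0.0, 0.0], [0.0, 0.0])
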