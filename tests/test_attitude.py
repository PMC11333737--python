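"""Kalman attitude estimation: pseudo-measurements, predict/update, filtering."""

import numpy as np
import pytest

from hrea.attitude import (
    ImuSample,
    ImuStream,
    KalmanConfig,
    PseudoMeasurement,
    estimate_attitude,
    kalman_predict,
    kalman_update,
    pseudo_measurement,
    wrap_angle,
)
from hrea.synthetic import NoiseSpec, attitude_to_imu

MAG_NORTH = np.array([22.0, 0.0, 42.0])


def sample(accel, gyro=(0, 0, 0), mag=MAG_NORTH, t=0.0):
    return ImuSample(np.asarray(accel, float), np.asarray(gyro, float),
                     np.asarray(mag, float), t)


class TestWrapAngle:
    @pytest.mark.parametrize("raw,expected", [
        (0.0, 0.0), (180.0, 180.0), (-180.0, 180.0), (190.0, -170.0),
        (-190.0, 170.0), (360.0, 0.0), (540.0, 180.0),
    ])
    def test_wraps_to_half_open_interval(self, raw, expected):
        assert wrap_angle(raw) == pytest.approx(expected)

    def test_array_output_in_range(self):
        a = wrap_angle(np.linspace(-1000, 1000, 999))
        assert np.all(a > -180) and np.all(a <= 180)


class TestPseudoMeasurement:
    def test_level_case(self):
        pm = pseudo_measurement(sample((0, 0, 1)))
        assert pm.roll_deg == pytest.approx(0.0)
        assert pm.pitch_deg == pytest.approx(0.0)

    def test_roll_45_from_accel(self):
        pm = pseudo_measurement(sample((0, 0.7071, 0.7071)))
        assert pm.roll_deg == pytest.approx(45.0, abs=1e-3)

    def test_yaw_zero_when_aligned_with_north(self):
        pm = pseudo_measurement(sample((0, 0, 1), mag=MAG_NORTH))
        assert pm.yaw_deg == pytest.approx(0.0, abs=1e-9)

    def test_rates_copied_from_gyro(self):
        pm = pseudo_measurement(sample((0, 0, 1), gyro=(1.0, -2.0, 3.0)))
        assert (pm.roll_rate_dps, pm.pitch_rate_dps, pm.yaw_rate_dps) == (1.0, -2.0, 3.0)

    def test_zero_accel_rejected(self):
        with pytest.raises(ValueError, match="unobservable"):
            pseudo_measurement(sample((0, 0, 0)))


class TestKalmanPredict:
    def test_constant_rate_integrates_angle(self):
        cfg = KalmanConfig(dt_s=1 / 30)
        x = np.array([10.0, 0, 0, 30.0, 0, 0])
        x2, _ = kalman_predict(x, np.eye(6), cfg)
        assert x2[0] == pytest.approx(11.0)

    def test_zero_rates_fix_angles(self):
        cfg = KalmanConfig()
        x = np.array([10.0, -20.0, 30.0, 0, 0, 0])
        x2, _ = kalman_predict(x, np.eye(6), cfg)
        assert np.allclose(x2, x)

    def test_covariance_propagation_with_zero_Q(self):
        cfg = KalmanConfig(Q=np.zeros((6, 6)))
        _, P2 = kalman_predict(np.zeros(6), np.eye(6), cfg)
        assert np.allclose(P2, cfg.F @ cfg.F.T)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            kalman_predict(np.zeros(5), np.eye(6), KalmanConfig())


class TestKalmanUpdate:
    def test_unit_covariance_gain_half(self):
        # P = R = H = I: gain 0.5, posterior halfway to the measurement
        cfg = KalmanConfig(R=np.eye(6))
        z = PseudoMeasurement(10.0, 0, 0, 0, 0, 0)
        x, P, K = kalman_update(np.zeros(6), np.eye(6), z, cfg)
        assert K[0, 0] == pytest.approx(0.5)
        assert x[0] == pytest.approx(5.0)

    def test_large_R_keeps_prior(self):
        cfg = KalmanConfig(R=1e12 * np.eye(6))
        z = PseudoMeasurement(10.0, 10.0, 10.0, 1, 1, 1)
        x, _, _ = kalman_update(np.zeros(6), np.eye(6), z, cfg)
        assert np.allclose(x, 0.0, atol=1e-9)

    def test_small_R_takes_measurement(self):
        cfg = KalmanConfig(R=1e-12 * np.eye(6))
        z = PseudoMeasurement(10.0, -5.0, 2.0, 1, 2, 3)
        x, _, _ = kalman_update(np.zeros(6), np.eye(6), z, cfg)
        assert np.allclose(x, z.as_array(), atol=1e-6)

    def test_innovation_takes_shortest_arc(self):
        cfg = KalmanConfig(R=np.eye(6))
        z = PseudoMeasurement(-175.0, 0, 0, 0, 0, 0)
        x, _, _ = kalman_update(np.array([175.0, 0, 0, 0, 0, 0]), np.eye(6), z, cfg)
        # innovation is +10 degrees across the wrap, not -350
        assert x[0] == pytest.approx(180.0)

    def test_singular_innovation_rejected(self):
        cfg = KalmanConfig(R=np.zeros((6, 6)))
        z = PseudoMeasurement(0, 0, 0, 0, 0, 0)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            kalman_update(np.zeros(6), np.zeros((6, 6)), z, cfg)


class TestEstimateAttitude:
    def test_static_stream_is_fixed_point(self):
        trace = np.zeros((90, 3))
        est = estimate_attitude(attitude_to_imu(trace, NoiseSpec(0, 0, 0, 0), 0))
        assert np.all(np.abs(est[:, :2]) < 1e-6)

    def test_constant_rate_ramp_recovered(self):
        t = np.arange(0, 4, 1 / 30)
        trace = np.zeros((len(t), 3))
        trace[:, 0] = 30.0 * t
        est = estimate_attitude(attitude_to_imu(trace, NoiseSpec(0, 0, 0, 0), 0))
        rmse = np.sqrt(np.mean((est[30:, 0] - trace[30:, 0]) ** 2))
        assert rmse < 0.5

    def test_filter_smooths_noisy_angles(self):
        rng = np.random.default_rng(3)
        t = np.arange(120) / 30
        truth = np.zeros((120, 3))
        truth[:, 0] = 20.0 * t
        noisy = truth + rng.normal(0, 3.0, truth.shape)
        stream = attitude_to_imu(noisy, NoiseSpec(0, 0, 0, 0), 0)
        est = estimate_attitude(stream)
        raw = np.array([pseudo_measurement(s).roll_deg for s in stream.samples()])
        f_rmse = np.sqrt(np.mean((est[30:, 0] - truth[30:, 0]) ** 2))
        r_rmse = np.sqrt(np.mean((raw[30:] - truth[30:, 0]) ** 2))
        assert f_rmse < r_rmse

    def test_covariance_stays_psd(self):
        cfg = KalmanConfig()
        rng = np.random.default_rng(11)
        x, P = np.zeros(6), cfg.P0.copy()
        for i in range(120):
            x, P = kalman_predict(x, P, cfg)
            z = PseudoMeasurement(*rng.normal(0, 3, 3), *rng.normal(0, 1, 3))
            x, P, _ = kalman_update(x, P, z, cfg)
            assert np.allclose(P, P.T)
            assert np.linalg.eigvalsh(P).min() >= -1e-9

    def test_matches_batch_least_squares_on_noiseless_window(self):
        # brute-force oracle: per-axis straight-line fit angle = a + b t over
        # the same 10 samples the filter consumed
        t = np.arange(10) / 30
        trace = np.zeros((10, 3))
        trace[:, 0] = 5.0 + 40.0 * t
        trace[:, 1] = -10.0 + 15.0 * t
        stream = attitude_to_imu(trace, NoiseSpec(0, 0, 0, 0), 0)
        est = estimate_attitude(stream)
        A = np.column_stack([np.ones(10), t])
        for axis in (0, 1):
            coef, *_ = np.linalg.lstsq(A, trace[:, axis], rcond=None)
            expected_final = coef[0] + coef[1] * t[-1]
            assert est[-1, axis] == pytest.approx(expected_final, abs=0.1)

    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ImuStream(
                time_s=np.array([0.0, 0.1, 0.05]),
                accel=np.tile([0, 0, 1.0], (3, 1)),
                gyro=np.zeros((3, 3)),
                mag=np.tile(MAG_NORTH, (3, 1)),
            )

    def test_short_stream_rejected(self):
        stream = ImuStream(
            time_s=np.array([0.0]), accel=np.array([[0, 0, 1.0]]),
            gyro=np.zeros((1, 3)), mag=MAG_NORTH[None],
        )
        with pytest.raises(ValueError, match="at least 2"):
            estimate_attitude(stream)
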