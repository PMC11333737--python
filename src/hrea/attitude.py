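"""Attitude estimation from 9-axis IMU streams with a linear Kalman filter.

The filter tracks a 6-dimensional state ``x = [roll, pitch, yaw,
roll_rate, pitch_rate, yaw_rate]`` (degrees, degrees/second).  Raw 9-axis
readings (accelerometer in g, gyroscope in deg/s, magnetometer in microtesla)
are first reduced to a 6-dimensional *pseudo-measurement*: roll and pitch from
the gravity direction sensed by the accelerometer, yaw from the
tilt-compensated magnetometer heading, and the angular rates copied from the
gyroscope.  With that reduction the observation model is exactly linear
(``H = I``) and the classic predict/update recursion applies unchanged.

The state-transition model is constant angular velocity: angles integrate
their rates over one sample period, rates persist.  All angles are kept in
``(-180, 180]`` and innovations are computed on the shortest angular arc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImuSample",
    "ImuStream",
    "AttitudeState",
    "PseudoMeasurement",
    "KalmanConfig",
    "wrap_angle",
    "pseudo_measurement",
    "kalman_predict",
    "kalman_update",
    "estimate_attitude",
]

#: indices of the angle components of the state / pseudo-measurement vector
_ANGLE_IDX = np.array([0, 1, 2])


def wrap_angle(a):
    """Wrap angles (degrees) to the interval ``(-180, 180]``."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class ImuSample:
    """One 9-axis IMU measurement.

    Attributes
    ----------
    accel : accelerometer reading, units of g (gravity), body frame.
    gyro : gyroscope reading, deg/s.
    mag : magnetometer reading, microtesla.
    time_s : sample timestamp in seconds.
    """

    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    time_s: float

    def __post_init__(self):
        for name in ("accel", "gyro", "mag"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, v)


@dataclass
class ImuStream:
    """A time-ordered stream of 9-axis samples stored as arrays.

    ``accel`` is (T, 3) in g, ``gyro`` (T, 3) in deg/s, ``mag`` (T, 3) in
    microtesla, ``time_s`` (T,) strictly increasing.
    """

    time_s: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        t = self.time_s
        for name in ("accel", "gyro", "mag"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (len(t), 3):
                raise ValueError(f"{name} must have shape ({len(t)}, 3)")
            setattr(self, name, v)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    def samples(self) -> Iterable[ImuSample]:
        for i in range(len(self)):
            yield ImuSample(self.accel[i], self.gyro[i], self.mag[i], float(self.time_s[i]))

    @staticmethod
    def from_samples(samples: Sequence[ImuSample]) -> "ImuStream":
        samples = list(samples)
        return ImuStream(
            time_s=np.array([s.time_s for s in samples]),
            accel=np.array([s.accel for s in samples]),
            gyro=np.array([s.gyro for s in samples]),
            mag=np.array([s.mag for s in samples]),
        )


@dataclass(frozen=True)
class AttitudeState:
    """Roll/pitch/yaw attitude (degrees) plus angular rates (deg/s)."""

    roll_deg: float
    pitch_deg: float
    yaw_deg: float
    roll_rate_dps: float
    pitch_rate_dps: float
    yaw_rate_dps: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.roll_deg,
                self.pitch_deg,
                self.yaw_deg,
                self.roll_rate_dps,
                self.pitch_rate_dps,
                self.yaw_rate_dps,
            ]
        )

    @staticmethod
    def from_array(x: np.ndarray) -> "AttitudeState":
        x = np.asarray(x, dtype=float)
        return AttitudeState(*wrap_angle(x[:3]), *x[3:6])


@dataclass(frozen=True)
class PseudoMeasurement:
    """Six-dimensional observation derived from one 9-axis sample.

    Roll/pitch come from the accelerometer gravity direction, yaw from the
    tilt-compensated magnetometer heading, rates straight from the gyroscope.
    """

    roll_deg: float
    pitch_deg: float
    yaw_deg: float
    roll_rate_dps: float
    pitch_rate_dps: float
    yaw_rate_dps: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.roll_deg,
                self.pitch_deg,
                self.yaw_deg,
                self.roll_rate_dps,
                self.pitch_rate_dps,
                self.yaw_rate_dps,
            ]
        )


def _default_F(dt_s: float) -> np.ndarray:
    F = np.eye(6)
    F[:3, 3:] = dt_s * np.eye(3)
    return F


@dataclass
class KalmanConfig:
    """Filter matrices and sampling period.

    Defaults: constant-angular-velocity transition, identity measurement
    matrix on the 6-dim pseudo-measurement, process noise 1e-3 deg^2 on the
    angles and 1e-2 (deg/s)^2 on the rates, measurement noise 4 deg^2 on the
    angles and 1 (deg/s)^2 on the rates, identity initial covariance.
    """

    dt_s: float = 1.0 / 30.0
    F: np.ndarray = None
    H: np.ndarray = None
    Q: np.ndarray = None
    R: np.ndarray = None
    P0: np.ndarray = None

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.F is None:
            self.F = _default_F(self.dt_s)
        if self.H is None:
            self.H = np.eye(6)
        if self.Q is None:
            self.Q = np.diag([1e-3] * 3 + [1e-2] * 3)
        if self.R is None:
            self.R = np.diag([4.0] * 3 + [1.0] * 3)
        if self.P0 is None:
            self.P0 = np.eye(6)
        for name in ("F", "H", "Q", "R", "P0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("Q", "R", "P0"):
            M = getattr(self, name)
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(M)) < -1e-9:
                raise ValueError(f"{name} must be positive semidefinite")
        if abs(np.linalg.det(self.F)) < 1e-12:
            raise ValueError("F must be invertible")


def pseudo_measurement(sample: ImuSample) -> PseudoMeasurement:
    """Reduce a 9-axis sample to the filter's 6-dim observation.

    roll = atan2(a_y, a_z), pitch = atan2(-a_x, sqrt(a_y^2 + a_z^2));
    yaw is the tilt-compensated magnetometer heading (0 deg when the level
    sensor's x-axis points along the reference horizontal field).
    """
    a = np.asarray(sample.accel, dtype=float)
    if np.linalg.norm(a) <= 0:
        raise ValueError("zero accelerometer vector: attitude unobservable")
    roll = np.arctan2(a[1], a[2])
    pitch = np.arctan2(-a[0], np.hypot(a[1], a[2]))

    # de-rotate the magnetometer into the horizontal plane, then take heading
    cr, sr = np.cos(roll), np.sin(roll)
    cp, sp = np.cos(pitch), np.sin(pitch)
    m = np.asarray(sample.mag, dtype=float)
    mx = cp * m[0] + sp * sr * m[1] + sp * cr * m[2]
    my = cr * m[1] - sr * m[2]
    yaw = np.arctan2(-my, mx)

    return PseudoMeasurement(
        roll_deg=float(np.degrees(roll)),
        pitch_deg=float(np.degrees(pitch)),
        yaw_deg=float(np.degrees(yaw)),
        roll_rate_dps=float(sample.gyro[0]),
        pitch_rate_dps=float(sample.gyro[1]),
        yaw_rate_dps=float(sample.gyro[2]),
    )


def kalman_predict(state: np.ndarray, covariance: np.ndarray, config: KalmanConfig):
    """Time update: ``x' = F x`` and ``P' = F P F^T + Q``."""
    state = np.asarray(state, dtype=float)
    P = np.asarray(covariance, dtype=float)
    F = config.F
    if state.shape != (F.shape[1],) or P.shape != F.shape:
        raise ValueError(
            f"dimension mismatch: state {state.shape}, P {P.shape}, F {F.shape}"
        )
    state_pred = F @ state
    P_pred = F @ P @ F.T + config.Q
    P_pred = 0.5 * (P_pred + P_pred.T)
    return state_pred, P_pred


def kalman_update(
    state: np.ndarray,
    covariance: np.ndarray,
    measurement: PseudoMeasurement,
    config: KalmanConfig,
):
    """Measurement update with wrap-aware innovation.

    ``K = P H^T (H P H^T + R)^-1``; ``x += K (z - H x)`` with the angle
    components of the innovation taken on the shortest arc;
    ``P = (I - K H) P`` (symmetrized).  Returns ``(state, covariance, gain)``.
    """
    x = np.asarray(state, dtype=float)
    P = np.asarray(covariance, dtype=float)
    H, R = config.H, config.R
    z = measurement.as_array()

    S = H @ P @ H.T + R
    # reject a numerically singular innovation covariance with a diagnostic
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"innovation covariance is singular (condition number {cond:.3e})"
        )
    K = P @ H.T @ np.linalg.inv(S)

    innovation = z - H @ x
    innovation[_ANGLE_IDX] = wrap_angle(innovation[_ANGLE_IDX])
    x_post = x + K @ innovation
    P_post = (np.eye(len(x)) - K @ H) @ P
    P_post = 0.5 * (P_post + P_post.T)
    return x_post, P_post, K


def estimate_attitude(stream, config: KalmanConfig | None = None) -> np.ndarray:
    """Run the filter over a stream; one state row per input sample.

    Parameters
    ----------
    stream : ImuStream or iterable of ImuSample.
    config : filter configuration; defaults for 30 Hz if omitted.

    Returns
    -------
    ndarray of shape (T, 6): columns roll, pitch, yaw (degrees, wrapped to
    ``(-180, 180]``) then the three angular rates (deg/s).  The first row is
    the pseudo-measurement of the first sample (filter initialization).
    """
    if config is None:
        config = KalmanConfig()
    if not isinstance(stream, ImuStream):
        stream = ImuStream.from_samples(list(stream))
    if len(stream) < 2:
        raise ValueError("need at least 2 samples to estimate attitude")

    out = np.empty((len(stream), 6))
    samples = list(stream.samples())
    x = pseudo_measurement(samples[0]).as_array()
    P = config.P0.copy()
    out[0] = x
    for i, s in enumerate(samples[1:], start=1):
        x, P = kalman_predict(x, P, config)
        z = pseudo_measurement(s)
        x, P, _ = kalman_update(x, P, z, config)
        out[i] = x
    out[:, :3] = wrap_angle(out[:, :3])
    return out
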