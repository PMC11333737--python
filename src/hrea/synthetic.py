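"""Synthetic scored rehabilitation-action recordings and raw IMU synthesis.

Emulates the study conditions: two 9-axis wearable sensors (#S1 on the
forearm, #S2 on the upper arm) sampled at 30 Hz while a participant performs
one of five upper-limb actions drawn from the Fugl-Meyer assessment, each
graded 0 (cannot perform), 1 (partial) or 2 (normal) by a clinician.

Each action has a *primary* channel — the sensor and attitude axis that
carries most of the movement.  Shoulder actions load the proximal sensor #S2;
elbow/forearm actions load the distal sensor #S1.  The non-primary sensor
receives a fixed leakage fraction of the primary trajectory plus independent
noise, so the two channels are complementary but correlated, which is what
makes decision fusion worthwhile.

The three clinical grades are operationalized as amplitude bands with
grade-specific artifacts: a normal movement reaches 90-100 % of the template
amplitude; a partial movement reaches 40-60 % and shows two velocity
reversals (hesitation jerks); a failed movement reaches only 5-15 % with a
3-degree tremor.  The bands are disjoint, so grades are separable by
amplitude alone — by design, since the clinical wording orders the grades by
how completely the movement is performed.

``attitude_to_imu`` forward-synthesizes a raw 9-axis stream from an attitude
trace (gravity direction for the accelerometer, finite-difference rates for
the gyroscope, a rotated fixed reference field for the magnetometer), giving
the attitude estimator a ground-truthed test input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .attitude import ImuStream, wrap_angle
from .recording import ActionRecording, AttitudeTrace

__all__ = [
    "ActionTemplate",
    "ScoreProfile",
    "NoiseSpec",
    "DEFAULT_TEMPLATES",
    "DEFAULT_PROFILES",
    "RATE_HZ",
    "ACTION_IDS",
    "generate_action",
    "generate_dataset",
    "attitude_to_imu",
]

RATE_HZ = 30.0
ACTION_IDS = ("A1", "A2", "A3", "A4", "A5")
_AXES = {"roll": 0, "pitch": 1, "yaw": 2}

#: reference magnetic field, microtesla: horizontal + vertical component
_MAG_REFERENCE = np.array([22.0, 0.0, 42.0])


@dataclass(frozen=True)
class ActionTemplate:
    """Kinematic template of one Fugl-Meyer action.

    ``primary_channel`` is ``(sensor_id, axis)`` with sensor in {"S1","S2"}
    and axis in {"roll","pitch","yaw"}.  The movement rises over ``rise_s``
    seconds (smoothstep), holds ``hold_s`` seconds at the peak, and returns
    over ``return_s`` seconds.
    """

    action_id: str
    primary_channel: Tuple[str, str]
    peak_amplitude_deg: float = 90.0
    rise_s: float = 2.0
    hold_s: float = 5.0
    return_s: float = 2.0
    leakage_fraction: float = 0.2

    def __post_init__(self):
        if self.action_id not in ACTION_IDS:
            raise ValueError(f"unknown action_id {self.action_id!r}")
        sensor, axis = self.primary_channel
        if sensor not in ("S1", "S2") or axis not in _AXES:
            raise ValueError(f"invalid primary_channel {self.primary_channel!r}")
        if not 0 < self.peak_amplitude_deg <= 180:
            raise ValueError("peak_amplitude_deg must be in (0, 180]")
        if self.rise_s + self.hold_s + self.return_s <= 0:
            raise ValueError("total duration must be positive")
        if not 0 <= self.leakage_fraction <= 1:
            raise ValueError("leakage_fraction must be in [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.rise_s + self.hold_s + self.return_s


@dataclass(frozen=True)
class ScoreProfile:
    """Operationalization of one clinical grade (0, 1 or 2)."""

    score: int
    amplitude_factor_range: Tuple[float, float]
    tremor_sd_deg: float = 0.0
    jerk_count: int = 0

    def __post_init__(self):
        if self.score not in (0, 1, 2):
            raise ValueError(f"score must be 0, 1 or 2, got {self.score}")
        lo, hi = self.amplitude_factor_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("amplitude_factor_range must be ordered within [0, 1]")
        if self.tremor_sd_deg < 0:
            raise ValueError("tremor_sd_deg must be non-negative")
        if self.jerk_count < 0:
            raise ValueError("jerk_count must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white-noise levels for raw IMU synthesis."""

    accel_sd_g: float = 0.02
    gyro_sd_dps: float = 0.5
    mag_sd_uT: float = 0.5
    angle_sd_deg: float = 1.0

    def __post_init__(self):
        for name in ("accel_sd_g", "gyro_sd_dps", "mag_sd_uT", "angle_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# Shoulder actions (A1 abduction, A4 flexion, A5 abduction to 90 deg) load the
# proximal upper-arm sensor #S2; elbow flexion (A2) and forearm rotation (A3)
# load the distal forearm sensor #S1.
DEFAULT_TEMPLATES: Dict[str, ActionTemplate] = {
    "A1": ActionTemplate("A1", ("S2", "roll"), peak_amplitude_deg=90.0),
    "A2": ActionTemplate("A2", ("S1", "pitch"), peak_amplitude_deg=100.0),
    "A3": ActionTemplate("A3", ("S1", "yaw"), peak_amplitude_deg=80.0),
    "A4": ActionTemplate("A4", ("S2", "pitch"), peak_amplitude_deg=90.0),
    "A5": ActionTemplate("A5", ("S2", "roll"), peak_amplitude_deg=90.0),
}

DEFAULT_PROFILES: Dict[int, ScoreProfile] = {
    0: ScoreProfile(0, (0.05, 0.15), tremor_sd_deg=3.0, jerk_count=0),
    1: ScoreProfile(1, (0.40, 0.60), tremor_sd_deg=1.0, jerk_count=2),
    2: ScoreProfile(2, (0.90, 1.00), tremor_sd_deg=0.0, jerk_count=0),
}

#: white angle noise added to every channel, degrees
_CHANNEL_NOISE_SD_DEG = 1.0


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _envelope(t: np.ndarray, tpl: ActionTemplate) -> np.ndarray:
    """Unit-amplitude rise/hold/return profile of the movement."""
    env = np.zeros_like(t)
    rise_end = tpl.rise_s
    hold_end = tpl.rise_s + tpl.hold_s
    if tpl.rise_s > 0:
        env = _smoothstep(t / tpl.rise_s)
    else:
        env = np.ones_like(t)
    hold = (t >= rise_end) & (t < hold_end)
    env[hold] = 1.0
    ret = t >= hold_end
    if tpl.return_s > 0:
        env[ret] = 1.0 - _smoothstep((t[ret] - hold_end) / tpl.return_s)
    else:
        env[ret] = 0.0
    return env


def _jerks(t: np.ndarray, tpl: ActionTemplate, count: int, rng: np.random.Generator) -> np.ndarray:
    """Hesitation artifacts: Gaussian dips during rise/return, each one
    forcing a velocity reversal."""
    dips = np.zeros_like(t)
    if count == 0:
        return dips
    phases: List[Tuple[float, float]] = []
    if tpl.rise_s > 0:
        phases.append((0.25 * tpl.rise_s, 0.9 * tpl.rise_s))
    if tpl.return_s > 0:
        start = tpl.rise_s + tpl.hold_s
        phases.append((start + 0.1 * tpl.return_s, start + 0.75 * tpl.return_s))
    if not phases:
        phases = [(0.0, tpl.duration_s)]
    width = 0.12  # seconds
    for k in range(count):
        lo, hi = phases[k % len(phases)]
        center = rng.uniform(lo, hi)
        dips += np.exp(-0.5 * ((t - center) / width) ** 2)
    return dips


def generate_action(
    action_id: str,
    score: int,
    seed: int,
    templates: Dict[str, ActionTemplate] | None = None,
    profiles: Dict[int, ScoreProfile] | None = None,
) -> ActionRecording:
    """Generate one two-channel 30 Hz attitude recording of a scored action.

    Deterministic given ``seed``.  The recording's ``meta`` dict carries the
    drawn amplitude factor and the effective peak amplitude in degrees.
    """
    templates = DEFAULT_TEMPLATES if templates is None else templates
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    if action_id not in templates:
        raise KeyError(f"unknown action_id {action_id!r}")
    if score not in profiles:
        raise KeyError(f"unknown score {score!r}")
    tpl = templates[action_id]
    prof = profiles[score]
    rng = np.random.default_rng(seed)

    n = int(round(tpl.duration_s * RATE_HZ))
    t = np.arange(n) / RATE_HZ

    factor = rng.uniform(*prof.amplitude_factor_range)
    amplitude = tpl.peak_amplitude_deg * factor

    env = _envelope(t, tpl)
    dips = _jerks(t, tpl, prof.jerk_count, rng)
    primary = amplitude * np.clip(env - 0.35 * dips, -1.0, 1.0)
    if prof.tremor_sd_deg > 0:
        primary = primary + rng.normal(0.0, prof.tremor_sd_deg, n)

    sensor, axis = tpl.primary_channel
    ax = _AXES[axis]
    angles = {
        "S1": np.zeros((n, 3)),
        "S2": np.zeros((n, 3)),
    }
    other = "S2" if sensor == "S1" else "S1"
    angles[sensor][:, ax] = primary
    angles[other][:, ax] = tpl.leakage_fraction * primary
    for sid in ("S1", "S2"):
        angles[sid] += rng.normal(0.0, _CHANNEL_NOISE_SD_DEG, (n, 3))
        angles[sid] = wrap_angle(angles[sid])

    return ActionRecording(
        trace_s1=AttitudeTrace("S1", angles["S1"], RATE_HZ),
        trace_s2=AttitudeTrace("S2", angles["S2"], RATE_HZ),
        action_id=action_id,
        score_label=score,
        meta={
            "seed": int(seed),
            "amplitude_factor": float(factor),
            "amplitude_deg": float(amplitude),
        },
    )


def generate_dataset(
    n_per_cell: int,
    seed: int,
    templates: Dict[str, ActionTemplate] | None = None,
    profiles: Dict[int, ScoreProfile] | None = None,
) -> List[ActionRecording]:
    """Balanced collection: 5 actions x 3 scores x ``n_per_cell`` recordings.

    Per-recording seeds are spawned deterministically from the master seed,
    so the collection is a pure function of its arguments.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    templates = DEFAULT_TEMPLATES if templates is None else templates
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(templates) * len(profiles) * n_per_cell) % (2**31)
    recordings = []
    i = 0
    for action_id in sorted(templates):
        for score in sorted(profiles):
            for _ in range(n_per_cell):
                recordings.append(
                    generate_action(action_id, score, int(child_seeds[i]), templates, profiles)
                )
                i += 1
    return recordings


def _euler_to_body(vec_w: np.ndarray, roll: np.ndarray, pitch: np.ndarray, yaw: np.ndarray) -> np.ndarray:
    """Rotate a world-frame vector into the body frame for each sample.

    Body-to-world rotation is Rz(yaw) Ry(pitch) Rx(roll); its transpose maps
    world to body.  Angles in radians, vectorized over samples.
    """
    cr, sr = np.cos(roll), np.sin(roll)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cy, sy = np.cos(yaw), np.sin(yaw)
    # rows of R^T = columns of R
    r00 = cy * cp
    r01 = sy * cp
    r02 = -sp
    r10 = cy * sp * sr - sy * cr
    r11 = sy * sp * sr + cy * cr
    r12 = cp * sr
    r20 = cy * sp * cr + sy * sr
    r21 = sy * sp * cr - cy * sr
    r22 = cp * cr
    vx, vy, vz = vec_w
    return np.stack(
        [
            r00 * vx + r01 * vy + r02 * vz,
            r10 * vx + r11 * vy + r12 * vz,
            r20 * vx + r21 * vy + r22 * vz,
        ],
        axis=1,
    )


def attitude_to_imu(
    attitude_trace: np.ndarray,
    noise_spec: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = RATE_HZ,
) -> ImuStream:
    """Forward-synthesize a raw 9-axis stream from a (T, 3) attitude trace.

    Accelerometer: body-frame gravity direction (unit magnitude in g) under
    the trace's roll/pitch.  Gyroscope: finite-difference angular rates of
    the (unwrapped) Euler angles, deg/s.  Magnetometer: body-frame rotation
    of a fixed reference field.  Deterministic given ``seed``.
    """
    trace = np.asarray(attitude_trace, dtype=float)
    if isinstance(attitude_trace, AttitudeTrace):
        trace = attitude_trace.samples
        rate_hz = attitude_trace.rate_hz
    if trace.ndim != 2 or trace.shape[1] != 3:
        raise ValueError("attitude trace must have shape (T, 3)")
    if trace.shape[0] < 2:
        raise ValueError("trace must have at least 2 samples (rates undefined)")
    noise_spec = NoiseSpec() if noise_spec is None else noise_spec
    rng = np.random.default_rng(seed)

    unwrapped = np.degrees(np.unwrap(np.radians(trace), axis=0))
    rad = np.radians(unwrapped)
    roll, pitch, yaw = rad[:, 0], rad[:, 1], rad[:, 2]
    n = trace.shape[0]
    t = np.arange(n) / rate_hz

    accel = _euler_to_body(np.array([0.0, 0.0, 1.0]), roll, pitch, yaw)
    gyro = np.gradient(unwrapped, 1.0 / rate_hz, axis=0)
    mag = _euler_to_body(_MAG_REFERENCE, roll, pitch, yaw)

    accel = accel + rng.normal(0.0, noise_spec.accel_sd_g, (n, 3))
    gyro = gyro + rng.normal(0.0, noise_spec.gyro_sd_dps, (n, 3))
    mag = mag + rng.normal(0.0, noise_spec.mag_sd_uT, (n, 3))
    return ImuStream(time_s=t, accel=accel, gyro=gyro, mag=mag)
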