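"""Roll/pitch estimation from 6-axis IMU data with a complementary filter.

The filter blends integrated gyroscope rates (trustworthy at high
frequency) with accelerometer tilt angles (trustworthy at low frequency)
through a constant blend coefficient ``a``::

    roll[n]  = a * (roll[n-1]  + gx[n] * dT) + (1 - a) * roll_raw[n]
    pitch[n] = a * (pitch[n-1] + gy[n] * dT) + (1 - a) * pitch_raw[n]

where the raw tilt angles come from the gravity direction::

    roll_raw  = atan2(ay, az)
    pitch_raw = atan2(-ax, sqrt(ay^2 + az^2))

Yaw is deliberately never produced: with the rotation axis parallel to
gravity the accelerometer carries no heading information, so absolute yaw
is unobservable without a magnetometer.  Angles are radians throughout;
convert to degrees only at presentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .sensor_model import SensorSample, SessionRecording

__all__ = [
    "DEFAULT_BLEND",
    "UndefinedAttitudeError",
    "OrientationState",
    "raw_angles",
    "initial_state",
    "complementary_update",
    "filter_session",
]

#: Default complementary-filter blend coefficient (dimensionless, in [0, 1]).
#: Values near 1 trust the integrated gyro; (1 - a) leaks in the
#: accelerometer tilt each update.
DEFAULT_BLEND = 0.98

_ZERO_NORM = 1e-9  # m/s^2; below this the attitude is undefined (free fall)


class UndefinedAttitudeError(ValueError):
    """Accelerometer vector is (numerically) zero: tilt is undefined."""


@dataclass(frozen=True)
class OrientationState:
    """Filter state after processing one sample."""

    roll: float
    pitch: float
    a: float = DEFAULT_BLEND
    last_time_ms: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"blend coefficient a={self.a} outside [0, 1]")
        if not (math.isfinite(self.roll) and math.isfinite(self.pitch)):
            raise ValueError("roll/pitch must be finite")


def raw_angles(ax: float, ay: float, az: float) -> tuple[float, float]:
    """Accelerometer-only tilt angles (roll_raw, pitch_raw) in radians.

    Invariant under uniform rescaling of the acceleration vector (atan2
    of ratios).  Raises :class:`UndefinedAttitudeError` for the all-zero
    vector (free fall), where tilt carries no information.
    """
    if math.sqrt(ax * ax + ay * ay + az * az) < _ZERO_NORM:
        raise UndefinedAttitudeError(
            "acceleration vector is zero; tilt angles undefined"
        )
    roll_raw = math.atan2(ay, az)
    pitch_raw = math.atan2(-ax, math.hypot(ay, az))
    return roll_raw, pitch_raw


def initial_state(sample: SensorSample, a: float = DEFAULT_BLEND) -> OrientationState:
    """State for the first sample of a session.

    Initializes roll/pitch to the raw accelerometer angles (no gyro term),
    so the filter starts unbiased for a static pose.
    """
    roll_raw, pitch_raw = raw_angles(sample.ax, sample.ay, sample.az)
    return OrientationState(roll=roll_raw, pitch=pitch_raw, a=a,
                            last_time_ms=sample.time_ms)


def complementary_update(
    state: OrientationState, sample: SensorSample
) -> OrientationState:
    """One discrete complementary-filter step.

    ``gx`` drives roll and ``gy`` drives pitch; dT comes from the sample
    time stamps (milliseconds converted to seconds).  In free fall (zero
    accelerometer vector) the previous filtered angles are kept unchanged
    and a warning is emitted.
    """
    if sample.time_ms <= state.last_time_ms:
        raise ValueError(
            f"non-increasing time stamp: {sample.time_ms} after {state.last_time_ms}"
        )
    dt = (sample.time_ms - state.last_time_ms) / 1000.0
    try:
        roll_raw, pitch_raw = raw_angles(sample.ax, sample.ay, sample.az)
    except UndefinedAttitudeError:
        warnings.warn(
            "zero acceleration vector; keeping previous filtered angles",
            stacklevel=2,
        )
        roll_raw, pitch_raw = state.roll, state.pitch
    a = state.a
    roll = a * (state.roll + sample.gx * dt) + (1.0 - a) * roll_raw
    pitch = a * (state.pitch + sample.gy * dt) + (1.0 - a) * pitch_raw
    return replace(state, roll=roll, pitch=pitch, last_time_ms=sample.time_ms)


def filter_session(
    session: SessionRecording, a: float = DEFAULT_BLEND
) -> tuple[np.ndarray, np.ndarray]:
    """Run the complementary filter over a whole session, vectorized.

    Returns ``(roll, pitch)`` arrays in radians, one value per sample,
    identical (to rounding) to iterating :func:`complementary_update`
    from :func:`initial_state`.

    The recurrence ``y[n] = a*y[n-1] + u[n]`` with input
    ``u[n] = a*g[n]*dT[n] + (1-a)*raw[n]`` is a first-order IIR filter and
    is evaluated with :func:`scipy.signal.lfilter`.  Sessions containing a
    (vanishingly rare) zero-acceleration sample fall back to the explicit
    loop so the free-fall handling matches the streaming API.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"blend coefficient a={a} outside [0, 1]")
    acc = session.accel
    gyro = session.gyro
    t = session.time_ms
    norms = np.linalg.norm(acc, axis=1)
    if (norms < _ZERO_NORM).any():
        return _filter_loop(session, a)

    roll_raw = np.arctan2(acc[:, 1], acc[:, 2])
    pitch_raw = np.arctan2(-acc[:, 0], np.hypot(acc[:, 1], acc[:, 2]))
    dt = np.empty(len(t))
    dt[0] = 0.0
    dt[1:] = np.diff(t) / 1000.0

    def _run(raw: np.ndarray, rate: np.ndarray) -> np.ndarray:
        u = a * rate * dt + (1.0 - a) * raw
        u[0] = raw[0]  # first sample initializes to the raw angle
        y = lfilter([1.0], [1.0, -a], u)
        return y

    return _run(roll_raw, gyro[:, 0]), _run(pitch_raw, gyro[:, 1])


def _filter_loop(session: SessionRecording, a: float) -> tuple[np.ndarray, np.ndarray]:
    samples = session.samples
    state = initial_state(samples[0], a=a)
    roll = np.empty(len(samples))
    pitch = np.empty(len(samples))
    roll[0], pitch[0] = state.roll, state.pitch
    for i, s in enumerate(samples[1:], start=1):
        state = complementary_update(state, s)
        roll[i], pitch[i] = state.roll, state.pitch
    return roll, pitch
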