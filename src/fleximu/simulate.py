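"""Synthetic multi-subject sensor-glove session generator.

Emulates the structure of the evaluation study's recordings: four
subjects, ~1-minute sessions sampled at 21 Hz, six kinematically distinct
periodic joint-mobility exercises, and anomalous variants (hand at rest
on the table, or only small residual movements).

Attitude is synthesized directly as roll/pitch trajectories and
differentiated for the gyro channels, so the complementary filter has a
recoverable ground truth.  The accelerometer reads gravity rotated into
the sensor frame plus a motion term and Gaussian noise; flex channels are
class-specific flexion waveforms quantized to integer ADC counts.

Subject individuality (amplitude/frequency multipliers, resting pose,
flex baselines) is the controlled source of the generalization gap: with
the default ``subject_variation`` leave-one-subject-out evaluation is
measurably harder than pooled k-fold, mirroring what happens when a model
trained on a few people meets a new hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .sensor_model import (
    ADC_MAX,
    ExerciseLabel,
    SessionRecording,
    SAMPLE_COLUMNS,
    write_session,
)

__all__ = [
    "GRAVITY",
    "AnomalyMode",
    "ExerciseKinematics",
    "EXERCISE_KINEMATICS",
    "SubjectProfile",
    "make_subject_profiles",
    "generate_session",
    "generate_dataset",
    "write_dataset",
]

GRAVITY = 9.81  # m/s^2

AnomalyMode = Literal["none", "rest", "low_motion"]

#: Default sensor-noise scales (1 sigma).
NOISE_ACCEL = 0.2   # m/s^2
NOISE_GYRO = 0.02   # rad/s
NOISE_FLEX = 8.0    # ADC counts

#: Residual movement of the incorrect-exercising mode relative to the
#: prescribed exercise.  Patients who are not doing the exercise still
#: move — anywhere from barely ("make only small movements") to almost
#: normal vigor while doing something else entirely — so the factor is
#: drawn per session from this range.  The overlap in summed movement
#: magnitude with correct sessions is what makes the crude two-criteria
#: features genuinely ambiguous, while the aimless waveform (uncoupled
#: channel rhythms) remains visible to a classifier that reads the
#: window shape.
LOW_MOTION_RANGE = (0.15, 0.7)

#: Session-to-session vigor of correct exercising.  Patients do not
#: reproduce an exercise at identical amplitude every session; each
#: correct session draws one overall movement-amplitude factor from this
#: range.
VIGOR_RANGE = (0.8, 1.15)


@dataclass(frozen=True)
class ExerciseKinematics:
    """Waveform template of one exercise class.

    Oscillation amplitudes are radians (attitude), rad/s (yaw rate),
    m/s^2 (linear motion) and ADC counts (flex excursion).  The six
    templates are pairwise distinguishable: for every pair of classes at
    least one channel's amplitude differs by several pooled standard
    deviations under the default subject variation.
    """

    freq: float            # base movement frequency, Hz
    roll_amp: float        # forearm pronation/supination swing, rad
    pitch_amp: float       # wrist/elbow flexion swing, rad
    roll_mean: float
    pitch_mean: float
    yaw_rate_amp: float    # rad/s
    accel_amp: float       # linear motion term, m/s^2
    flex_base: tuple[float, float]      # thumb, middle finger, ADC counts
    flex_exc: tuple[float, float]       # excursion, ADC counts
    flex_phase: float      # flexion phase relative to the attitude cycle, rad


# Templates follow the exercise instructions: "rolling" is forearm
# pronation/supination (large roll swing), "wrist flexion-extension" and
# "hand up-down" are pitch-dominant at different vigor, "wrist and
# fingers extension" and "hand kneading" are flexion-dominant with small
# whole-hand motion, "basket" is a moderate hand-turning pattern with
# bent, nearly static fingers.
EXERCISE_KINEMATICS: dict[ExerciseLabel, ExerciseKinematics] = {
    ExerciseLabel.BASKET: ExerciseKinematics(
        freq=0.80, roll_amp=0.90, pitch_amp=0.15, roll_mean=0.10, pitch_mean=0.05,
        yaw_rate_amp=0.30, accel_amp=0.60,
        flex_base=(2200, 2300), flex_exc=(150, 200), flex_phase=0.0,
    ),
    ExerciseLabel.WRIST_FLEXION_EXTENSION: ExerciseKinematics(
        freq=0.50, roll_amp=0.10, pitch_amp=0.70, roll_mean=0.00, pitch_mean=0.20,
        yaw_rate_amp=0.05, accel_amp=0.40,
        flex_base=(1800, 1900), flex_exc=(500, 600), flex_phase=np.pi / 2,
    ),
    ExerciseLabel.WRIST_FINGERS_EXTENSION: ExerciseKinematics(
        freq=0.50, roll_amp=0.08, pitch_amp=0.25, roll_mean=0.00, pitch_mean=0.10,
        yaw_rate_amp=0.05, accel_amp=0.15,
        flex_base=(1500, 1600), flex_exc=(1200, 1400), flex_phase=0.0,
    ),
    ExerciseLabel.ROLLING: ExerciseKinematics(
        freq=0.60, roll_amp=1.30, pitch_amp=0.10, roll_mean=0.00, pitch_mean=0.05,
        yaw_rate_amp=0.60, accel_amp=0.35,
        flex_base=(2600, 2500), flex_exc=(250, 150), flex_phase=0.0,
    ),
    ExerciseLabel.HAND_UP_DOWN: ExerciseKinematics(
        freq=0.45, roll_amp=0.12, pitch_amp=1.10, roll_mean=0.05, pitch_mean=0.30,
        yaw_rate_amp=0.10, accel_amp=0.90,
        flex_base=(2000, 2400), flex_exc=(700, 500), flex_phase=np.pi / 2,
    ),
    ExerciseLabel.HAND_KNEADING: ExerciseKinematics(
        freq=0.45, roll_amp=0.30, pitch_amp=0.50, roll_mean=0.00, pitch_mean=0.15,
        yaw_rate_amp=0.15, accel_amp=0.25,
        flex_base=(1300, 1700), flex_exc=(1600, 1100), flex_phase=np.pi,
    ),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Fixed per-subject idiosyncrasies applied on top of the templates."""

    subject_id: str
    attitude_scale: float = 1.0     # multiplies roll/pitch swing
    gyro_scale: float = 1.0         # multiplies yaw-rate swing
    accel_scale: float = 1.0        # multiplies the linear-motion term
    flex_scale: float = 1.0         # multiplies flex excursion
    freq_scale: float = 1.0         # multiplies movement frequency
    rest_roll: float = 0.0          # resting pose, rad
    rest_pitch: float = 0.0
    flex_base_shift: float = 0.0    # ADC counts added to both baselines
    phase: float = 0.0              # habitual phase offset, rad
    noise_accel: float = NOISE_ACCEL
    noise_gyro: float = NOISE_GYRO
    noise_flex: float = NOISE_FLEX

    def __post_init__(self) -> None:
        if not 0 < self.freq_scale * 2.0 < 4.0:
            raise ValueError("frequency scale out of plausible range")


def make_subject_profiles(
    n_subjects: int,
    variation: float = 0.12,
    seed: int | np.random.SeedSequence = 0,
) -> list[SubjectProfile]:
    """Draw fixed subject profiles.

    ``variation`` is the relative spread of the per-subject amplitude and
    frequency multipliers (clipped to [0.7, 1.3] at the default spread);
    resting pose and flex baseline shifts scale with it too.  Larger
    variation widens the gap between pooled k-fold and
    leave-one-subject-out performance.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 1.0 - 2.5 * variation, 1.0 + 2.5 * variation
    profiles = []
    for i in range(n_subjects):
        mult = np.clip(rng.normal(1.0, variation, size=5), lo, hi)
        profiles.append(SubjectProfile(
            subject_id=f"s{i + 1:02d}",
            attitude_scale=float(mult[0]),
            gyro_scale=float(mult[1]),
            accel_scale=float(mult[2]),
            flex_scale=float(mult[3]),
            freq_scale=float(np.clip(mult[4], 0.75, 1.25)),
            rest_roll=float(rng.normal(0.0, 1.5 * variation)),
            rest_pitch=float(rng.normal(0.0, 1.5 * variation)),
            flex_base_shift=float(rng.normal(0.0, 2500.0 * variation)),
            phase=float(rng.uniform(0, 2 * np.pi)),
        ))
    return profiles


def _gravity_in_body(roll: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Specific force of gravity in the sensor frame for given tilt.

    Chosen so the accelerometer tilt formulas recover roll and pitch
    exactly in the noise-free static case.
    """
    ax = -GRAVITY * np.sin(pitch)
    ay = GRAVITY * np.sin(roll) * np.cos(pitch)
    az = GRAVITY * np.cos(roll) * np.cos(pitch)
    return np.column_stack([ax, ay, az])


def generate_session(
    profile: SubjectProfile,
    exercise: ExerciseLabel,
    anomaly_mode: AnomalyMode = "none",
    duration: float = 60.0,
    fs: float = 21.0,
    seed: int | np.random.SeedSequence = 0,
) -> SessionRecording:
    """Simulate one labelled training session.

    ``rest`` holds the hand static at the subject's resting pose (noise
    only); ``low_motion`` performs the exercise at a small residual
    amplitude drawn from :data:`LOW_MOTION_RANGE`.  Equal seeds give
    identical sessions.
    """
    if anomaly_mode not in ("none", "rest", "low_motion"):
        raise ValueError(f"unknown anomaly mode {anomaly_mode!r}")
    kin = EXERCISE_KINEMATICS[exercise]
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    time_ms = np.round(np.arange(n) * 1000.0 / fs).astype(np.int64)

    if anomaly_mode == "none":
        scale = float(rng.uniform(*VIGOR_RANGE))
    elif anomaly_mode == "rest":
        scale = 0.0
    else:
        scale = float(rng.uniform(*LOW_MOTION_RANGE))
    w = 2 * np.pi * kin.freq * profile.freq_scale
    ph = profile.phase
    if anomaly_mode == "low_motion":
        # aimless small movements: residual amplitudes follow the class
        # scale, but the rhythm and the coupling between joints do not —
        # each channel group gets its own frequency and phase
        w_att = 2 * np.pi * rng.uniform(0.2, 0.9) * profile.freq_scale
        w_flex = 2 * np.pi * rng.uniform(0.2, 0.9) * profile.freq_scale
        ph_roll, ph_pitch, ph_yaw, ph_flex = rng.uniform(0, 2 * np.pi, 4)
    else:
        w_att = w_flex = w
        ph_roll = ph
        ph_pitch = ph + np.pi / 3
        ph_yaw = ph + np.pi / 5
        ph_flex = ph + kin.flex_phase

    roll_amp = kin.roll_amp * profile.attitude_scale * scale
    pitch_amp = kin.pitch_amp * profile.attitude_scale * scale
    roll0 = profile.rest_roll + kin.roll_mean * scale
    pitch0 = profile.rest_pitch + kin.pitch_mean * scale

    roll = roll0 + roll_amp * np.sin(w_att * t + ph_roll)
    pitch = pitch0 + pitch_amp * np.sin(w_att * t + ph_pitch)
    droll = roll_amp * w_att * np.cos(w_att * t + ph_roll)
    dpitch = pitch_amp * w_att * np.cos(w_att * t + ph_pitch)

    gx = droll + rng.normal(0, profile.noise_gyro, n)
    gy = dpitch + rng.normal(0, profile.noise_gyro, n)
    gz = (kin.yaw_rate_amp * profile.gyro_scale * scale
          * np.sin(w_att * t + ph_yaw)
          + rng.normal(0, profile.noise_gyro, n))

    acc = _gravity_in_body(roll, pitch)
    m = kin.accel_amp * profile.accel_scale * scale
    # linear motion at twice the movement frequency (push + return per cycle)
    acc[:, 0] += m * np.sin(2 * w_att * t + ph_roll)
    acc[:, 1] += 0.6 * m * np.cos(2 * w_att * t + ph_roll + 0.7)
    acc[:, 2] += 0.8 * m * np.sin(2 * w_att * t + ph_roll + 1.9)
    acc += rng.normal(0, profile.noise_accel, (n, 3))

    flex = np.empty((n, 2))
    flex_wave = 0.5 * (1.0 + np.sin(w_flex * t + ph_flex))
    for j in range(2):
        base = kin.flex_base[j] + profile.flex_base_shift
        exc = kin.flex_exc[j] * profile.flex_scale * scale
        flex[:, j] = base + exc * flex_wave + rng.normal(0, profile.noise_flex, n)
    flex = np.clip(np.rint(flex), 0, ADC_MAX).astype(np.int64)

    df = pd.DataFrame({
        "time_ms": time_ms,
        "ax": acc[:, 0], "ay": acc[:, 1], "az": acc[:, 2],
        "gx": gx, "gy": gy, "gz": gz,
        "f1": flex[:, 0], "f2": flex[:, 1],
    }, columns=list(SAMPLE_COLUMNS))
    return SessionRecording(
        subject_id=profile.subject_id,
        exercise=exercise,
        anomalous=anomaly_mode != "none",
        fs=fs,
        data=df,
    )


def generate_dataset(
    n_subjects: int = 4,
    n_sessions: int = 292,
    n_anomalous: int = 96,
    duration_mean: float = 79.0,
    duration_spread: float | None = None,
    fs: float = 21.0,
    subject_variation: float = 0.12,
    seed: int = 0,
) -> tuple[list[SessionRecording], pd.DataFrame]:
    """Generate a full multi-subject study dataset.

    Defaults mirror the evaluation study's scale: 292 sessions from 4
    subjects, 96 of them anomalous, ~79 s average duration at 21 Hz.
    Correct sessions cycle through the six exercises per subject
    (balanced coverage); anomalous sessions alternate between the rest
    and low-motion modes.  Durations are uniform on
    ``duration_mean ± duration_spread``.

    Returns the sessions and a manifest with one row per file
    (file_id, subject, exercise, anomalous, mode, duration_s).
    """
    if n_sessions <= 0 or not 0 <= n_anomalous <= n_sessions:
        raise ValueError("need 0 <= n_anomalous <= n_sessions, n_sessions > 0")
    if duration_spread is None:
        duration_spread = 0.24 * duration_mean  # 79 s -> +/- 19 s
    if duration_mean - duration_spread < 4.0:
        raise ValueError("shortest session must be at least 4 s")
    root = np.random.SeedSequence(seed)
    prof_ss, sess_ss = root.spawn(2)
    profiles = make_subject_profiles(n_subjects, subject_variation, prof_ss)
    rng = np.random.default_rng(sess_ss)
    session_seeds = np.random.SeedSequence(
        entropy=int(rng.integers(2 ** 31))).spawn(n_sessions)

    labels = list(ExerciseLabel)
    plan: list[tuple[SubjectProfile, ExerciseLabel, AnomalyMode]] = []
    n_correct = n_sessions - n_anomalous
    for i in range(n_correct):
        plan.append((profiles[i % n_subjects],
                     labels[(i // n_subjects) % len(labels)], "none"))
    for i in range(n_anomalous):
        mode: AnomalyMode = "rest" if i % 2 == 0 else "low_motion"
        plan.append((profiles[i % n_subjects],
                     labels[(i // n_subjects) % len(labels)], mode))

    sessions: list[SessionRecording] = []
    rows = []
    for i, (profile, exercise, mode) in enumerate(plan):
        duration = rng.uniform(duration_mean - duration_spread,
                               duration_mean + duration_spread)
        s = generate_session(profile, exercise, anomaly_mode=mode,
                             duration=duration, fs=fs, seed=session_seeds[i])
        sessions.append(s)
        rows.append({
            "file_id": f"session_{i:04d}",
            "subject": profile.subject_id,
            "exercise": exercise.value,
            "anomalous": int(mode != "none"),
            "mode": mode,
            "duration_s": round(duration, 3),
        })
    return sessions, pd.DataFrame(rows)


def write_dataset(
    sessions: Sequence[SessionRecording],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write session CSVs and the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for s, file_id in zip(sessions, manifest["file_id"]):
        p = out_dir / f"{file_id}.csv"
        write_session(s, p)
        paths.append(p.name)
    manifest.insert(0, "path", paths)
    mpath = out_dir / "manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath
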