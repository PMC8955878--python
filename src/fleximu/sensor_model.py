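"""Domain types for sensor-glove recordings and tabular session I/O.

A recording session is a time-stamped stream of 8-channel glove readings:
3-axis acceleration (m/s^2), 3-axis angular velocity (rad/s) and two raw
flex-sensor ADC counts (12-bit, 0-4095).  Whole sessions carry a single
exercise label and an anomaly flag; that whole-file labelling is what the
downstream fragmenting and evaluation code relies on.

Sessions are serialized as one CSV file each, with session metadata in
``# key: value`` comment lines before the header row.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ADC_MAX",
    "SAMPLE_COLUMNS",
    "VHISTORY_COLUMNS",
    "SessionFormatError",
    "SessionValidationError",
    "ExerciseLabel",
    "SensorSample",
    "SessionRecording",
    "VHistoryRecord",
    "read_session",
    "write_session",
    "read_vhistory",
    "write_vhistory",
]

#: Full-scale raw reading of the glove's 12-bit ADC.
ADC_MAX = 4095

#: Column order of the per-sample session CSV.
SAMPLE_COLUMNS = ("time_ms", "ax", "ay", "az", "gx", "gy", "gz", "f1", "f2")

#: Column order of a serialized vhistory stream: the 10-element feature
#: vector followed by [time, anomalyclass] (12 values per record).
VHISTORY_COLUMNS = (
    "ax", "ay", "az", "f1", "f2", "gx", "gy", "gz", "roll", "pitch",
    "time_ms", "anomalyclass",
)

_FLOAT_FMT = "%.6f"


class SessionFormatError(ValueError):
    """Raised when a session file cannot be parsed (header or layout)."""


class SessionValidationError(ValueError):
    """Raised when session content violates a domain invariant."""


class ExerciseLabel(enum.Enum):
    """The six joint-mobility exercises the glove distinguishes.

    Definition order is the canonical class order used for classifier
    output vectors and confusion-matrix axes.
    """

    BASKET = "basket"
    WRIST_FLEXION_EXTENSION = "wrist_flexion_extension"
    WRIST_FINGERS_EXTENSION = "wrist_fingers_extension"
    ROLLING = "rolling"
    HAND_UP_DOWN = "hand_up_down"
    HAND_KNEADING = "hand_kneading"

    @property
    def index(self) -> int:
        """Position of this label in the canonical class order."""
        return _LABEL_ORDER.index(self)

    @classmethod
    def from_string(cls, value: str) -> "ExerciseLabel":
        try:
            return cls(value.strip().lower())
        except ValueError:
            names = ", ".join(m.value for m in cls)
            raise SessionFormatError(
                f"unknown exercise label {value!r}; expected one of: {names}"
            ) from None


_LABEL_ORDER: tuple[ExerciseLabel, ...] = tuple(ExerciseLabel)


@dataclass(frozen=True)
class SensorSample:
    """One time-stamped 8-channel glove reading."""

    time_ms: int
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float
    f1: int
    f2: int

    def validate(self) -> None:
        for name in ("f1", "f2"):
            v = getattr(self, name)
            if not 0 <= v <= ADC_MAX:
                raise SessionValidationError(
                    f"{name}={v} outside raw ADC range [0, {ADC_MAX}]"
                )
        imu = (self.ax, self.ay, self.az, self.gx, self.gy, self.gz)
        if not all(np.isfinite(imu)):
            raise SessionValidationError(f"non-finite IMU channel in {self}")


@dataclass
class SessionRecording:
    """A labelled ~1-minute training session.

    ``data`` holds one row per sample in :data:`SAMPLE_COLUMNS` order; the
    whole file carries one exercise label and one anomaly flag.
    """

    subject_id: str
    exercise: ExerciseLabel
    anomalous: bool
    fs: float
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.exercise, ExerciseLabel):
            self.exercise = ExerciseLabel.from_string(str(self.exercise))
        missing = [c for c in SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SessionFormatError(f"session data missing columns: {missing}")
        self.data = self.data.loc[:, list(SAMPLE_COLUMNS)].reset_index(drop=True)
        _validate_arrays(self.data)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_samples(
        cls,
        subject_id: str,
        exercise: ExerciseLabel,
        anomalous: bool,
        fs: float,
        samples: Sequence[SensorSample],
    ) -> "SessionRecording":
        rows = [
            (s.time_ms, s.ax, s.ay, s.az, s.gx, s.gy, s.gz, s.f1, s.f2)
            for s in samples
        ]
        df = pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))
        return cls(subject_id, exercise, anomalous, fs, df)

    # -- access ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, i: int) -> SensorSample:
        row = self.data.iloc[i]
        return SensorSample(
            time_ms=int(row["time_ms"]),
            ax=float(row["ax"]), ay=float(row["ay"]), az=float(row["az"]),
            gx=float(row["gx"]), gy=float(row["gy"]), gz=float(row["gz"]),
            f1=int(row["f1"]), f2=int(row["f2"]),
        )

    @property
    def samples(self) -> list[SensorSample]:
        return [self[i] for i in range(len(self))]

    @property
    def time_ms(self) -> np.ndarray:
        return self.data["time_ms"].to_numpy(dtype=np.int64)

    @property
    def accel(self) -> np.ndarray:
        """(N, 3) acceleration in m/s^2."""
        return self.data[["ax", "ay", "az"]].to_numpy(dtype=float)

    @property
    def gyro(self) -> np.ndarray:
        """(N, 3) angular velocity in rad/s."""
        return self.data[["gx", "gy", "gz"]].to_numpy(dtype=float)

    @property
    def flex(self) -> np.ndarray:
        """(N, 2) raw flex ADC counts."""
        return self.data[["f1", "f2"]].to_numpy(dtype=float)


def _validate_arrays(df: pd.DataFrame) -> None:
    if len(df) == 0:
        raise SessionValidationError("session must contain at least one sample")
    t = df["time_ms"].to_numpy()
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        i = int(bad[0]) + 1
        raise SessionValidationError(
            f"time_ms not strictly increasing at row {i} "
            f"({t[i - 1]} -> {t[i]})"
        )
    for name in ("f1", "f2"):
        v = df[name].to_numpy()
        out = np.flatnonzero((v < 0) | (v > ADC_MAX))
        if out.size:
            i = int(out[0])
            raise SessionValidationError(
                f"{name}={v[i]} at row {i} outside raw ADC range [0, {ADC_MAX}]"
            )
    imu = df[["ax", "ay", "az", "gx", "gy", "gz"]].to_numpy(dtype=float)
    if not np.isfinite(imu).all():
        i = int(np.flatnonzero(~np.isfinite(imu).all(axis=1))[0])
        raise SessionValidationError(f"non-finite IMU channel at row {i}")


@dataclass(frozen=True)
class VHistoryRecord:
    """One record of the on-device output stream.

    Layout is the 10-element feature vector v followed by
    ``[time_ms, anomalyclass]`` — 12 values per record; ``anomalyclass`` is
    the anomaly-classification score in [0, 1] (1 = correct exercising).
    """

    v: tuple[float, ...]
    time_ms: int
    anomalyclass: float

    def __post_init__(self) -> None:
        if len(self.v) != 10:
            raise SessionValidationError(
                f"feature vector must have 10 elements, got {len(self.v)}"
            )
        if not 0.0 <= self.anomalyclass <= 1.0:
            raise SessionValidationError(
                f"anomalyclass={self.anomalyclass} outside [0, 1]"
            )

    def as_row(self) -> tuple:
        return (*self.v, self.time_ms, self.anomalyclass)


# -- session file I/O ----------------------------------------------------

_HEADER_KEYS = ("subject", "exercise", "anomalous", "fs")


def write_session(session: SessionRecording, path: str | Path) -> None:
    """Write one session as a CSV with a ``# key: value`` metadata header.

    Floats carry 6 decimal places; time is integer milliseconds.  The file
    round-trips through :func:`read_session` losslessly at that precision.
    """
    _validate_arrays(session.data)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# subject: {session.subject_id}\n")
        fh.write(f"# exercise: {session.exercise.value}\n")
        fh.write(f"# anomalous: {int(session.anomalous)}\n")
        fh.write(f"# fs: {session.fs:g}\n")
        out = session.data.copy()
        for c in ("time_ms", "f1", "f2"):
            out[c] = out[c].astype(np.int64)
        out.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_session(path: str | Path) -> SessionRecording:
    """Read a session CSV written by :func:`write_session`.

    Raises :class:`SessionFormatError` on a malformed header and
    :class:`SessionValidationError` (naming the offending row) when the
    content breaks an invariant; invariant violations are never silently
    repaired.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" not in line:
                    raise SessionFormatError(
                        f"{path}: malformed metadata line {line.strip()!r}"
                    )
                key, _, value = line.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise SessionFormatError(f"{path}: header missing keys {missing}")
    if not body_lines:
        raise SessionFormatError(f"{path}: no data rows")
    try:
        df = pd.read_csv(io.StringIO("".join(body_lines)))
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise SessionFormatError(f"{path}: unreadable CSV body: {exc}") from exc
    if list(df.columns) != list(SAMPLE_COLUMNS):
        raise SessionFormatError(
            f"{path}: expected columns {list(SAMPLE_COLUMNS)}, got {list(df.columns)}"
        )
    try:
        fs = float(meta["fs"])
        anomalous = bool(int(meta["anomalous"]))
    except ValueError as exc:
        raise SessionFormatError(f"{path}: malformed header value: {exc}") from exc
    return SessionRecording(
        subject_id=meta["subject"],
        exercise=ExerciseLabel.from_string(meta["exercise"]),
        anomalous=anomalous,
        fs=fs,
        data=df,
    )


# -- vhistory stream I/O -------------------------------------------------

def write_vhistory(records: Iterable[VHistoryRecord], path: str | Path) -> None:
    """Serialize a vhistory stream as a 12-column CSV."""
    rows = [r.as_row() for r in records]
    df = pd.DataFrame(rows, columns=list(VHISTORY_COLUMNS))
    df["time_ms"] = df["time_ms"].astype(np.int64)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_vhistory(path: str | Path) -> list[VHistoryRecord]:
    df = pd.read_csv(path)
    if list(df.columns) != list(VHISTORY_COLUMNS):
        raise SessionFormatError(
            f"{path}: expected columns {list(VHISTORY_COLUMNS)}"
        )
    return [
        VHistoryRecord(
            v=tuple(float(row[c]) for c in VHISTORY_COLUMNS[:10]),
            time_ms=int(row["time_ms"]),
            anomalyclass=float(row["anomalyclass"]),
        )
        for _, row in df.iterrows()
    ]
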