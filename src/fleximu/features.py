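"""Feature construction for windowed glove-data classification.

Three feature families are built here:

* the 10-channel per-sample feature vector
  ``v = [ax, ay, az, f1, f2, gx, gy, gz, roll, pitch]`` and the ``Ns x 10``
  window matrices cut from it (row ``i`` is ``v[n - Ns + i]``, oldest
  first);
* the two hand-crafted window criteria — ``s_acc``, the summed L1 length
  of the acceleration vectors, and ``s_flex``, the summed absolute
  smoothed difference of the flex signals — cheap enough for the simplest
  microcontrollers;
* train-only min-max scaling of window columns.

Flex channels enter ``v`` as raw ADC counts; no physical calibration is
attempted (flex-sensor resistance is nonlinear in bend angle, but the
classifiers only need a monotone correlate of finger flexion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import gaussian

from .orientation import DEFAULT_BLEND, OrientationState, filter_session
from .sensor_model import SensorSample, SessionRecording, VHistoryRecord

__all__ = [
    "CHANNELS",
    "N_CHANNELS",
    "SmoothingKernel",
    "DEFAULT_KERNEL",
    "build_kernel",
    "s_acc",
    "s_flex",
    "make_feature_vector",
    "make_vhistory_record",
    "feature_matrix",
    "extract_windows",
    "ScalerParams",
    "fit_scaler",
    "apply_scaler",
]

#: Canonical channel order of the feature vector v.
CHANNELS = ("ax", "ay", "az", "f1", "f2", "gx", "gy", "gz", "roll", "pitch")
N_CHANNELS = len(CHANNELS)


@dataclass(frozen=True)
class SmoothingKernel:
    """A zero-sum, antisymmetric smoothed-difference kernel.

    Convolving a signal with this kernel yields a noise-robust estimate of
    its local change: constants are annihilated (coefficients sum to 0)
    and the antisymmetry ``h[k] = -h[L-1-k]`` makes the absolute response
    invariant to reversing the kernel.
    """

    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        h = np.asarray(self.coefficients, dtype=float)
        if h.ndim != 1 or h.size < 2:
            raise ValueError("kernel must be a 1-D sequence of >= 2 coefficients")
        if abs(h.sum()) > 0.05 * np.abs(h).sum() + 1e-12:
            raise ValueError(f"kernel coefficients must sum to ~0, got {h.sum()}")
        if not np.allclose(h, -h[::-1], atol=0.05):
            raise ValueError("kernel must be antisymmetric: h[k] = -h[L-1-k]")

    def __len__(self) -> int:
        return len(self.coefficients)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)


def build_kernel(
    size: int = 3,
    sigma: float = 0.9,
    scale: float = -2.0,
    round_to: int | None = 1,
) -> SmoothingKernel:
    """Derive the flex-smoothing kernel from a Gaussian.

    A ``size``-tap Gaussian with standard deviation ``sigma`` is
    normalized to unit sum, differentiated by full convolution with the
    difference filter ``[-1, 1]``, multiplied by ``scale`` and (by
    default) rounded half-away-from-zero to one decimal.  The defaults
    (3, 0.9, -2) yield ``[0.5, 0.4, -0.4, -0.5]``.

    Pass ``round_to=None`` to keep the exact coefficients for analysis.
    """
    if size % 2 == 0 or size < 3:
        raise ValueError(f"kernel size must be an odd integer >= 3, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    g = gaussian(size, std=sigma)
    g = g / g.sum()
    h = scale * np.convolve(g, [-1.0, 1.0], mode="full")
    if round_to is not None:
        # round half away from zero, reproducing the printed coefficients
        q = 10.0 ** round_to
        h = np.copysign(np.floor(np.abs(h) * q + 0.5) / q, h)
    return SmoothingKernel(tuple(float(c) for c in h))


#: Kernel used on the device: build_kernel(3, 0.9, -2).
DEFAULT_KERNEL = build_kernel()


def _accel_array(window) -> np.ndarray:
    if isinstance(window, SessionRecording):
        return window.accel
    if isinstance(window, np.ndarray):
        return np.asarray(window, dtype=float)
    return np.array([(s.ax, s.ay, s.az) for s in window], dtype=float)


def _flex_sum_array(window) -> np.ndarray:
    if isinstance(window, SessionRecording):
        return window.flex.sum(axis=1)
    arr = np.asarray(window, dtype=float) if isinstance(window, np.ndarray) else None
    if arr is not None:
        if arr.ndim == 2 and arr.shape[1] == 2:
            return arr.sum(axis=1)
        if arr.ndim == 1:
            return arr
        raise ValueError(f"expected (N, 2) flex array or 1-D sum, got {arr.shape}")
    return np.array([s.f1 + s.f2 for s in window], dtype=float)


def s_acc(window, ns: int | None = None) -> float:
    """Summed L1 length of the acceleration vectors over a window.

    ``window`` may be a sequence of :class:`SensorSample`, a
    :class:`SessionRecording` slice, or an ``(N, 3)`` acceleration array.
    Large values mean vigorous whole-hand movement.
    """
    acc = _accel_array(window)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError(f"expected (N, 3) acceleration data, got {acc.shape}")
    if ns is not None and len(acc) != ns:
        raise ValueError(f"window has {len(acc)} samples, expected Ns={ns}")
    if len(acc) == 0:
        raise ValueError("empty window")
    return float(np.abs(acc).sum())


def s_flex(window, kernel: SmoothingKernel = DEFAULT_KERNEL,
           ns: int | None = None) -> float:
    """Summed absolute smoothed difference of the flex signals.

    The two flex channels are summed sample-wise (convolution is
    distributive, so filtering ``f1 + f2`` equals the sum of the filtered
    channels) and convolved with the smoothed-difference kernel at fully
    overlapping ("valid") positions only; the absolute responses are
    summed.  Constant flex readings give exactly 0; finger motion gives a
    positive score growing with flexion change.
    """
    x = _flex_sum_array(window)
    if ns is not None and len(x) != ns:
        raise ValueError(f"window has {len(x)} samples, expected Ns={ns}")
    if len(x) < len(kernel):
        raise ValueError(
            f"window of {len(x)} samples shorter than kernel ({len(kernel)})"
        )
    y = np.convolve(x, kernel.array, mode="valid")
    return float(np.abs(y).sum())


def make_feature_vector(sample: SensorSample, state: OrientationState) -> np.ndarray:
    """Assemble the 10-element feature vector v for one sample.

    The orientation state must already be updated through this sample.
    Flex values stay raw ADC counts; scaling happens only at the min-max
    scaler.
    """
    return np.array(
        [sample.ax, sample.ay, sample.az, float(sample.f1), float(sample.f2),
         sample.gx, sample.gy, sample.gz, state.roll, state.pitch],
        dtype=float,
    )


def make_vhistory_record(
    sample: SensorSample, state: OrientationState, anomalyclass: float
) -> VHistoryRecord:
    """Concatenate v with [time, anomalyclass] into a 12-value record."""
    v = make_feature_vector(sample, state)
    return VHistoryRecord(v=tuple(v), time_ms=sample.time_ms,
                          anomalyclass=float(anomalyclass))


def feature_matrix(session: SessionRecording, a: float = DEFAULT_BLEND) -> np.ndarray:
    """Per-sample feature vectors for a whole session, shape (N, 10).

    Runs the complementary filter over the session and stacks the channels
    in canonical order.
    """
    roll, pitch = filter_session(session, a=a)
    acc = session.accel
    flex = session.flex
    gyro = session.gyro
    return np.column_stack([acc, flex, gyro, roll, pitch])


def extract_windows(features: np.ndarray, ns: int, stride: int = 1) -> np.ndarray:
    """All windows of ``ns`` consecutive feature vectors, oldest row first.

    Returns a strided view of shape ``(n_windows, ns, n_channels)``;
    ``stride=1`` gives the single-sample-shifted windows used at test
    time, ``stride=ns`` the disjoint fragments used for tree training.
    """
    features = np.asarray(features)
    if features.ndim != 2:
        raise ValueError(f"expected (N, C) feature matrix, got {features.shape}")
    if len(features) < ns:
        raise ValueError(f"only {len(features)} samples for window Ns={ns}")
    view = sliding_window_view(features, ns, axis=0)  # (N-ns+1, C, ns)
    return view[::stride].transpose(0, 2, 1)


@dataclass(frozen=True)
class ScalerParams:
    """Per-channel min-max bounds learned from training data only."""

    xmin: np.ndarray
    xmax: np.ndarray

    def __post_init__(self) -> None:
        xmin = np.asarray(self.xmin, dtype=float)
        xmax = np.asarray(self.xmax, dtype=float)
        if xmin.shape != xmax.shape or xmin.ndim != 1:
            raise ValueError("xmin/xmax must be 1-D arrays of equal length")
        if (xmax < xmin).any():
            raise ValueError("xmax must be >= xmin for every channel")
        object.__setattr__(self, "xmin", xmin)
        object.__setattr__(self, "xmax", xmax)

    @property
    def n_channels(self) -> int:
        return len(self.xmin)

    # -- serialization so models ship with their scaler ------------------

    def to_dict(self) -> dict:
        return {"xmin": self.xmin.tolist(), "xmax": self.xmax.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(xmin=np.asarray(d["xmin"]), xmax=np.asarray(d["xmax"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ScalerParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_scaler(training_vectors: np.ndarray | Sequence[np.ndarray]) -> ScalerParams:
    """Learn per-channel min/max from training feature vectors only.

    Fitting on test data would leak its range into the model; callers fit
    per cross-validation fold on the training files alone.
    """
    X = np.asarray(training_vectors, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need at least 2 training vectors to fit a scaler")
    return ScalerParams(xmin=X.min(axis=0), xmax=X.max(axis=0))


def apply_scaler(M: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Column-wise min-max scaling ``(x - xmin) / (xmax - xmin)``.

    Accepts a single ``(Ns, C)`` window or a batch ``(B, Ns, C)``.
    Training-range values map into [0, 1]; test values may fall outside.
    A degenerate channel (``xmax == xmin``) maps to 0.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[-1] != params.n_channels:
        raise ValueError(
            f"matrix has {M.shape[-1]} channels, scaler has {params.n_channels}"
        )
    span = params.xmax - params.xmin
    safe = np.where(span == 0.0, 1.0, span)
    out = (M - params.xmin) / safe
    if (span == 0.0).any():
        out = np.where(span == 0.0, 0.0, out)
    return out
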