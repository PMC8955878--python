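"""Window classifiers: a two-criteria decision tree and two small CNNs.

Two model families decide whether a patient is exercising correctly:

* a depth-limited decision tree over the hand-crafted pair
  ``(s_acc, s_flex)`` — cheap enough for the weakest microcontrollers;
* a small temporal convolutional network over the scaled ``Ns x 10``
  window matrix, with a 6-way softmax head for exercise-type
  classification and a 1-unit sigmoid head for binary anomaly
  classification (1 = correct exercising).  The two heads share an
  identical trunk, so anomaly training can warm-start from exercise
  weights.

Training batches are drawn the way the study data was fragmented: each
matrix in a batch comes from a uniformly random training file at a
uniformly random valid start index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from . import features as F
from .convnet import LayerSizes, AdamOptimizer, TinyConvNet
from .features import DEFAULT_KERNEL, ScalerParams, SmoothingKernel, apply_scaler
from .sensor_model import ExerciseLabel, SessionRecording

__all__ = [
    "TwoCriteria",
    "TreeModel",
    "NetSpec",
    "TrainConfig",
    "TrainedNet",
    "FileFeatures",
    "LeakageError",
    "featurize_session",
    "compute_fragment_criteria",
    "train_tree",
    "tree_predict",
    "build_net",
    "train_net",
    "predict_exercise",
    "predict_anomaly",
    "binarize_anomaly_score",
]

Task = Literal["exercise", "anomaly"]


class LeakageError(RuntimeError):
    """A test file leaked into a training set."""


@dataclass(frozen=True)
class TwoCriteria:
    """The hand-crafted criteria pair for one data fragment."""

    s_acc: float
    s_flex: float

    def __post_init__(self) -> None:
        if self.s_acc < 0 or self.s_flex < 0:
            raise ValueError("criteria are sums of absolute values; must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.s_acc, self.s_flex])


@dataclass
class FileFeatures:
    """Per-file feature matrix plus whole-file labels.

    The unit of cross-validation splitting: windows are never built
    across file boundaries, and splits assign whole files to train or
    test.
    """

    file_id: str
    subject_id: str
    exercise: ExerciseLabel
    correct: bool          # True = correct exercising (anomalyclass 1)
    fs: float
    features: np.ndarray   # (N, C) feature matrix
    accel: np.ndarray = field(repr=False, default=None)  # (N, 3) for s_acc
    flex_sum: np.ndarray = field(repr=False, default=None)  # (N,) f1+f2


def featurize_session(
    session: SessionRecording, file_id: str, a: float | None = None
) -> FileFeatures:
    """Extract the (N, 10) feature matrix and criteria inputs for one file."""
    kwargs = {} if a is None else {"a": a}
    feats = F.feature_matrix(session, **kwargs)
    return FileFeatures(
        file_id=file_id,
        subject_id=session.subject_id,
        exercise=session.exercise,
        correct=not session.anomalous,
        fs=session.fs,
        features=feats,
        accel=session.accel,
        flex_sum=session.flex.sum(axis=1),
    )


# -- two-criteria fragments ---------------------------------------------

def compute_fragment_criteria(
    session: SessionRecording | FileFeatures,
    ns: int,
    overlapping: bool,
    kernel: SmoothingKernel = DEFAULT_KERNEL,
) -> tuple[np.ndarray, ExerciseLabel, bool]:
    """Criteria for every fragment of a file.

    Non-overlapping mode cuts ``floor(L / Ns)`` disjoint fragments (tree
    training); overlapping mode slides a single-sample-shifted window for
    ``L - Ns + 1`` fragments (testing).  Returns an ``(n_fragments, 2)``
    array of ``(s_acc, s_flex)`` plus the file's exercise label and
    correctness flag (whole-file labelling).
    """
    if isinstance(session, FileFeatures):
        accel, flex_sum = session.accel, session.flex_sum
        exercise, correct = session.exercise, session.correct
    else:
        accel, flex_sum = session.accel, session.flex.sum(axis=1)
        exercise, correct = session.exercise, not session.anomalous
    L = len(accel)
    if L < ns:
        warnings.warn(f"file shorter ({L}) than window Ns={ns}; no fragments")
        return np.empty((0, 2)), exercise, correct

    stride = 1 if overlapping else ns
    # moving sums over precomputed per-sample terms: L1 acceleration and
    # |smoothed difference| of the flex sum
    acc_l1 = np.abs(accel).sum(axis=1)
    sacc_all = np.convolve(acc_l1, np.ones(ns), mode="valid")
    resp = np.abs(np.convolve(flex_sum, kernel.array, mode="valid"))
    k = ns - len(kernel) + 1  # valid conv positions inside one window
    sflex_all = np.convolve(resp, np.ones(k), mode="valid")
    starts = np.arange(0, L - ns + 1, stride)
    crit = np.column_stack([sacc_all[starts], sflex_all[starts]])
    return crit, exercise, correct


# -- decision tree -------------------------------------------------------

@dataclass
class TreeModel:
    """Depth-limited binary tree over (s_acc, s_flex)."""

    clf: DecisionTreeClassifier
    max_depth: int = 3

    @property
    def depth(self) -> int:
        return int(self.clf.get_depth())


def train_tree(X: np.ndarray, y: np.ndarray, seed: int = 0,
               max_depth: int = 3) -> TreeModel:
    """Fit the anomaly tree (gini criterion, best splits, depth <= 3).

    ``X`` is (n, 2) criteria, ``y`` binary labels (1 = correct).  Both
    classes must be present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, k) with one label per row")
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    clf = DecisionTreeClassifier(
        criterion="gini", splitter="best", max_depth=max_depth,
        random_state=seed,
    )
    clf.fit(X, y)
    return TreeModel(clf=clf, max_depth=max_depth)


def tree_predict(model: TreeModel, c: TwoCriteria | np.ndarray) -> int | np.ndarray:
    """Deterministic traversal; ties at split thresholds go left (<=)."""
    x = c.as_array()[None, :] if isinstance(c, TwoCriteria) else np.asarray(c, float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    pred = model.clf.predict(x)
    return int(pred[0]) if single else pred.astype(int)


# -- convolutional networks ----------------------------------------------

@dataclass(frozen=True)
class NetSpec:
    """Architecture description of one classifier network.

    The trunk is a temporal convolution stack over the window axis with
    the feature channels as input channels; only the head differs between
    tasks.  Parameter count is capped at 5,000 to respect the ~10 kB
    compiled footprint of microcontroller deployment.
    """

    task: Task
    ns: int
    n_channels: int = F.N_CHANNELS
    sizes: LayerSizes = LayerSizes()
    param_cap: int = 5000

    def __post_init__(self) -> None:
        if self.task not in ("exercise", "anomaly"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.ns < 10:
            raise ValueError(f"window Ns={self.ns} below minimum 10")
        if self.param_count > self.param_cap:
            raise ValueError(
                f"{self.param_count} parameters exceed the cap {self.param_cap}"
            )

    @property
    def n_out(self) -> int:
        return len(ExerciseLabel) if self.task == "exercise" else 1

    @property
    def param_count(self) -> int:
        f1, f2 = self.sizes.conv_filters
        w, d = self.sizes.conv_width, self.sizes.dense
        return (w * self.n_channels * f1 + f1) + (w * f1 * f2 + f2) \
            + (f2 * d + d) + (d * self.n_out + self.n_out)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, lr 0.001; loss follows the task)."""

    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 50
    steps_per_epoch: int = 100
    seed: int = 0


@dataclass
class TrainedNet:
    """A trained network bundled with its scaler and label order."""

    spec: NetSpec
    net: TinyConvNet
    scaler: ScalerParams
    label_order: tuple[str, ...]
    loss_trace: list[float] = field(default_factory=list)


def build_net(task: Task, ns: int, n_channels: int = F.N_CHANNELS,
              sizes: LayerSizes = LayerSizes(), seed: int = 0) -> TrainedNet:
    """Freshly initialized network for a task (identity scaler placeholder)."""
    spec = NetSpec(task=task, ns=ns, n_channels=n_channels, sizes=sizes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E65]))
    net = TinyConvNet(ns=ns, n_channels=n_channels, n_out=spec.n_out,
                      sizes=sizes, rng=rng)
    scaler = ScalerParams(xmin=np.zeros(n_channels), xmax=np.ones(n_channels))
    return TrainedNet(spec=spec, net=net, scaler=scaler,
                      label_order=tuple(m.value for m in ExerciseLabel))


def _window_label(f: FileFeatures, task: Task) -> int:
    return f.exercise.index if task == "exercise" else int(f.correct)


def train_net(
    spec: NetSpec,
    train_files: Sequence[FileFeatures],
    config: TrainConfig,
    scaler: ScalerParams,
    init_from: TrainedNet | None = None,
    forbidden_ids: set[str] | None = None,
    channel_indices: Sequence[int] | None = None,
) -> TrainedNet:
    """Train a network by randomly sampled window batches.

    Every batch matrix comes from a uniformly random training file at a
    uniformly random valid start index, scaled with the train-only
    min-max scaler.  One master seed fans out to the init and batch
    generators, so equal seeds give identical loss traces.  ``init_from``
    warm-starts the trunk (e.g. anomaly model from exercise weights).
    ``forbidden_ids`` guards against test files leaking into training.
    ``channel_indices`` selects retained feature columns (ablation).
    """
    if forbidden_ids:
        leaked = [f.file_id for f in train_files if f.file_id in forbidden_ids]
        if leaked:
            raise LeakageError(f"test files present in training set: {leaked}")
    if not train_files:
        raise ValueError("empty training set")

    cols = np.asarray(channel_indices if channel_indices is not None
                      else np.arange(spec.n_channels))
    if len(cols) != spec.n_channels:
        raise ValueError("channel_indices length must match spec.n_channels")

    ss = np.random.SeedSequence([config.seed & 0x7FFFFFFF])
    init_ss, batch_ss = ss.spawn(2)
    net = TinyConvNet(ns=spec.ns, n_channels=spec.n_channels, n_out=spec.n_out,
                      sizes=spec.sizes, rng=np.random.default_rng(init_ss))
    if init_from is not None:
        net.copy_trunk_from(init_from.net)
    opt = AdamOptimizer(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(batch_ss)

    usable = [f for f in train_files if len(f.features) >= spec.ns]
    if not usable:
        raise ValueError(f"no training file long enough for Ns={spec.ns}")
    # one contiguous scaled array with per-file offsets lets a whole batch
    # be gathered with a single fancy index
    feats = [f.features[:, cols] for f in usable]
    big = apply_scaler(np.concatenate(feats, axis=0), scaler)
    offsets = np.concatenate([[0], np.cumsum([len(x) for x in feats])[:-1]])
    labels = np.array([_window_label(f, spec.task) for f in usable])
    max_start = np.array([len(x) - spec.ns for x in feats])
    rel = np.arange(spec.ns)

    trace: list[float] = []
    for _ in range(config.epochs):
        epoch_loss = 0.0
        for _ in range(config.steps_per_epoch):
            fi = rng.integers(0, len(feats), size=config.batch_size)
            starts = offsets[fi] + rng.integers(0, max_start[fi] + 1)
            X = big[starts[:, None] + rel[None, :], :]
            loss, grads = net.loss_and_grads(X, labels[fi])
            opt.step(net.params, grads)
            epoch_loss += loss
        trace.append(epoch_loss / config.steps_per_epoch)

    return TrainedNet(spec=spec, net=net, scaler=scaler,
                      label_order=tuple(m.value for m in ExerciseLabel),
                      loss_trace=trace)


def predict_exercise(model: TrainedNet, m_scaled: np.ndarray) -> np.ndarray:
    """Class probabilities (6-vector per window; rows sum to 1).

    ``m_scaled`` must already be scaled with the model's scaler; accepts
    one (Ns, C) window or a (B, Ns, C) batch.
    """
    if model.spec.task != "exercise":
        raise ValueError("model was built for the anomaly task")
    x = _check_input(model, m_scaled)
    out = model.net.predict(x)
    return out[0] if np.asarray(m_scaled).ndim == 2 else out


def predict_anomaly(model: TrainedNet, m_scaled: np.ndarray) -> float | np.ndarray:
    """Anomaly score in [0, 1] per window; 1 means correct exercising."""
    if model.spec.task != "anomaly":
        raise ValueError("model was built for the exercise task")
    x = _check_input(model, m_scaled)
    out = model.net.predict(x)[:, 0]
    return float(out[0]) if np.asarray(m_scaled).ndim == 2 else out


def binarize_anomaly_score(score: float | np.ndarray, threshold: float = 0.5):
    """Binary anomalyclass: 1 (correct) iff score >= threshold (ties correct)."""
    arr = np.asarray(score)
    out = (arr >= threshold).astype(int)
    return int(out) if arr.ndim == 0 else out


def save_model(model: TrainedNet, out_dir) -> None:
    """Write a self-describing model bundle (spec + weights + scaler)."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = model.spec
    meta = {
        "task": spec.task,
        "ns": spec.ns,
        "n_channels": spec.n_channels,
        "sizes": {
            "conv_filters": list(spec.sizes.conv_filters),
            "conv_width": spec.sizes.conv_width,
            "pool": spec.sizes.pool,
            "dense": spec.sizes.dense,
        },
        "label_order": list(model.label_order),
        "param_count": spec.param_count,
    }
    (out / "spec.json").write_text(json.dumps(meta, indent=1))
    model.scaler.save(out / "scaler.json")
    np.savez(out / "weights.npz", **model.net.params)


def load_model(in_dir) -> TrainedNet:
    import json
    from pathlib import Path

    src = Path(in_dir)
    meta = json.loads((src / "spec.json").read_text())
    sizes = LayerSizes(
        conv_filters=tuple(meta["sizes"]["conv_filters"]),
        conv_width=meta["sizes"]["conv_width"],
        pool=meta["sizes"]["pool"],
        dense=meta["sizes"]["dense"],
    )
    spec = NetSpec(task=meta["task"], ns=meta["ns"],
                   n_channels=meta["n_channels"], sizes=sizes)
    net = TinyConvNet(ns=spec.ns, n_channels=spec.n_channels,
                      n_out=spec.n_out, sizes=sizes,
                      rng=np.random.default_rng(0))
    with np.load(src / "weights.npz") as z:
        net.params = {k: z[k].copy() for k in z.files}
    scaler = ScalerParams.load(src / "scaler.json")
    return TrainedNet(spec=spec, net=net, scaler=scaler,
                      label_order=tuple(meta["label_order"]))


def _check_input(model: TrainedNet, m: np.ndarray) -> np.ndarray:
    x = np.asarray(m, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1] != model.spec.ns or x.shape[2] != model.spec.n_channels:
        raise ValueError(
            f"expected windows of shape ({model.spec.ns}, {model.spec.n_channels}), "
            f"got {x.shape}"
        )
    return x
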