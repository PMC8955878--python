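"""Cross-validation, ablation and metrics for the glove classifiers.

Implements the study protocol end to end: whole files are the unit of
splitting (5-fold shuffled partition, or leave-one-subject-out), models
and scalers are fitted per fold on training files only, and testing uses
overlapping single-sample-shifted fragments of the test files.  Named
ablation cases drop sensor-channel groups and retrain from scratch,
simulating a simplified glove construction.

Metrics are precision, recall, f1 and accuracy — binary with the
"correct exercise" class as positive for the anomaly task, support-
weighted one-vs-rest averages for the 6-way exercise task — plus
row-normalized confusion matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

from . import features as F
from .classifiers import (
    FileFeatures,
    LeakageError,
    NetSpec,
    TrainConfig,
    TrainedNet,
    binarize_anomaly_score,
    compute_fragment_criteria,
    featurize_session,
    train_net,
    train_tree,
    tree_predict,
)
from .features import DEFAULT_KERNEL, SmoothingKernel, apply_scaler, fit_scaler
from .sensor_model import ExerciseLabel, SessionRecording

__all__ = [
    "SplitPlan",
    "AblationCase",
    "ABLATION_CASES",
    "EvalReport",
    "plan_five_fold",
    "plan_loso",
    "apply_ablation",
    "classification_metrics",
    "confusion",
    "featurize_dataset",
    "run_experiment",
    "report_markdown",
]

Scheme = Literal["five_fold", "loso"]
METRIC_NAMES = ("precision", "recall", "f1", "accuracy")


@dataclass(frozen=True)
class SplitPlan:
    """Train/test file-index sets for each cross-validation fold."""

    scheme: Scheme
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        for train, test in self.folds:
            if set(train) & set(test):
                raise LeakageError("fold has overlapping train and test sets")

    def __len__(self) -> int:
        return len(self.folds)


def plan_five_fold(file_ids: Sequence[str], seed: int = 0) -> SplitPlan:
    """Shuffled 5-way partition of files; each fold tests a different ~20%."""
    n = len(file_ids)
    if n < 5:
        raise ValueError(f"need at least 5 files for 5-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parts = np.array_split(order, 5)
    folds = []
    for k in range(5):
        test = tuple(int(i) for i in parts[k])
        train = tuple(int(i) for j, p in enumerate(parts) if j != k for i in p)
        folds.append((train, test))
    return SplitPlan(scheme="five_fold", folds=tuple(folds))


def plan_loso(subject_ids: Sequence[str]) -> SplitPlan:
    """One fold per subject (sorted ids); the fold tests that subject only."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for s in subjects:
        test = tuple(i for i, sid in enumerate(subject_ids) if sid == s)
        train = tuple(i for i, sid in enumerate(subject_ids) if sid != s)
        folds.append((train, test))
    return SplitPlan(scheme="loso", folds=tuple(folds))


@dataclass(frozen=True)
class AblationCase:
    """A named sensor-channel subset (simplified glove construction)."""

    name: str
    retained: tuple[str, ...]

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(F.CHANNELS.index(c) for c in self.retained)


def _case(name: str, dropped: tuple[str, ...]) -> AblationCase:
    return AblationCase(name, tuple(c for c in F.CHANNELS if c not in dropped))


ABLATION_CASES: dict[str, AblationCase] = {
    "normal": _case("normal", ()),
    "noflex": _case("noflex", ("f1", "f2")),
    "nogyro": _case("nogyro", ("gx", "gy", "gz")),
    "noaccel": _case("noaccel", ("ax", "ay", "az")),
    "noangles": _case("noangles", ("roll", "pitch")),
    "noimu": _case("noimu", ("gx", "gy", "gz", "ax", "ay", "az", "roll", "pitch")),
}


def apply_ablation(M: np.ndarray, case: AblationCase | str) -> np.ndarray:
    """Drop the ablated columns of a window matrix (physically narrower)."""
    if isinstance(case, str):
        if case not in ABLATION_CASES:
            raise ValueError(f"unknown ablation case {case!r}")
        case = ABLATION_CASES[case]
    M = np.asarray(M)
    if M.shape[-1] != F.N_CHANNELS:
        raise ValueError(f"expected {F.N_CHANNELS} channels, got {M.shape[-1]}")
    return M[..., list(case.indices)]


# -- metrics -------------------------------------------------------------

def classification_metrics(
    predictions: Sequence[int], labels: Sequence[int],
    task: Literal["anomaly", "exercise"],
) -> dict[str, float]:
    """Precision/recall/f1/accuracy for one fold.

    Anomaly task: binary metrics with the correct-exercise class (label
    1) as positive.  Exercise task: per-class one-vs-rest metrics
    averaged with the true-instance count (support) as weight.  Accuracy
    is the plain fraction of correct predictions in both tasks.
    """
    y_pred = np.asarray(predictions, dtype=int)
    y_true = np.asarray(labels, dtype=int)
    if len(y_pred) == 0 or len(y_pred) != len(y_true):
        raise ValueError("predictions and labels must be equal-length, non-empty")
    if task == "anomaly":
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", pos_label=1, zero_division=0)
    elif task == "exercise":
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0)
    else:
        raise ValueError(f"unknown task {task!r}")
    return {
        "precision": float(p),
        "recall": float(r),
        "f1": float(f1),
        "accuracy": float(accuracy_score(y_true, y_pred)),
    }


def confusion(predictions: Sequence[int], labels: Sequence[int],
              n_classes: int = len(ExerciseLabel)) -> np.ndarray:
    """Row-normalized confusion matrix: cell[i, j] = P(pred j | true i).

    Rows without any true instance stay all-zero (with a warning) rather
    than NaN.
    """
    cm = confusion_matrix(labels, predictions, labels=np.arange(n_classes))
    support = cm.sum(axis=1, keepdims=True)
    if (support == 0).any():
        empty = [int(i) for i in np.flatnonzero(support[:, 0] == 0)]
        warnings.warn(f"classes with zero support in confusion matrix: {empty}")
    return np.divide(cm, support, out=np.zeros(cm.shape, dtype=float),
                     where=support > 0)


@dataclass
class EvalReport:
    """Per-fold and aggregated metrics for one experiment."""

    scheme: Scheme
    model_kind: str
    task: str
    ns: int
    ablation: str
    fold_metrics: list[dict[str, float]]
    confusion_matrix: np.ndarray | None = None
    label_order: tuple[str, ...] = tuple(m.value for m in ExerciseLabel)

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Sample mean and (n-1)-denominator std of each metric across folds."""
        out = {}
        for m in METRIC_NAMES:
            vals = np.array([fm[m] for fm in self.fold_metrics])
            std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[m] = (float(vals.mean()), std)
        return out

    def mean(self, metric: str = "accuracy") -> float:
        return self.aggregate()[metric][0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, fm in enumerate(self.fold_metrics):
            rows.append({"scheme": self.scheme, "model": self.model_kind,
                         "task": self.task, "ns": self.ns,
                         "ablation": self.ablation, "fold": k, **fm})
        return pd.DataFrame(rows)


# -- experiment driver ---------------------------------------------------

def featurize_dataset(
    sessions: Sequence[SessionRecording],
    file_ids: Sequence[str] | None = None,
    a: float | None = None,
) -> list[FileFeatures]:
    """Feature matrices for a whole dataset (do once, reuse across folds)."""
    if file_ids is None:
        file_ids = [f"session_{i:04d}" for i in range(len(sessions))]
    return [featurize_session(s, fid, a=a) for s, fid in zip(sessions, file_ids)]


def _predict_windows_cnn(model: TrainedNet, f: FileFeatures,
                         cols: Sequence[int]) -> np.ndarray:
    wins = F.extract_windows(f.features[:, list(cols)], model.spec.ns, stride=1)
    out = model.net.predict(apply_scaler(wins, model.scaler))
    if model.spec.task == "exercise":
        return out.argmax(axis=1)
    return binarize_anomaly_score(out[:, 0])


def run_experiment(
    dataset: Sequence[SessionRecording] | Sequence[FileFeatures],
    model_kind: Literal["tree", "cnn"],
    task: Literal["exercise", "anomaly"],
    ns: int,
    ablation: str | AblationCase,
    plan: SplitPlan,
    config: TrainConfig | None = None,
    kernel: SmoothingKernel = DEFAULT_KERNEL,
) -> EvalReport:
    """Train and evaluate one model configuration across all folds.

    The dataset index order must match the plan.  Exercise-type
    experiments use the correct-exercise files only; anomaly experiments
    use everything with the binary correctness label.  Scalers and models
    see training files only; testing walks the overlapping fragments of
    each test file.
    """
    if model_kind == "tree" and task != "anomaly":
        raise ValueError("the two-criteria tree only supports the anomaly task")
    case = ablation if isinstance(ablation, AblationCase) else ABLATION_CASES[ablation]
    config = config or TrainConfig()
    files = [f if isinstance(f, FileFeatures) else featurize_session(f, f"session_{i:04d}")
             for i, f in enumerate(dataset)]

    fold_metrics: list[dict[str, float]] = []
    cm_counts = np.zeros((len(ExerciseLabel), len(ExerciseLabel)), dtype=int)

    for k, (train_idx, test_idx) in enumerate(plan.folds):
        train = [files[i] for i in train_idx]
        test = [files[i] for i in test_idx]
        if task == "exercise":
            train = [f for f in train if f.correct]
            test = [f for f in test if f.correct]
        if not train or not test:
            raise ValueError(f"fold {k} has an empty train or test set")
        test_ids = {f.file_id for f in test}

        if model_kind == "cnn":
            y_true, y_pred = _run_fold_cnn(train, test, test_ids, task, ns,
                                           case, config, fold=k)
        else:
            y_true, y_pred = _run_fold_tree(train, test, ns, case, kernel,
                                            config.seed if config else 0)
        fold_metrics.append(classification_metrics(y_pred, y_true, task))
        if task == "exercise":
            cm_counts += confusion_matrix(
                y_true, y_pred, labels=np.arange(len(ExerciseLabel)))

    cm = None
    if task == "exercise":
        support = cm_counts.sum(axis=1, keepdims=True)
        cm = np.divide(cm_counts, support, out=np.zeros(cm_counts.shape),
                       where=support > 0)
    return EvalReport(
        scheme=plan.scheme, model_kind=model_kind, task=task, ns=ns,
        ablation=case.name, fold_metrics=fold_metrics, confusion_matrix=cm,
    )


def _run_fold_cnn(train, test, test_ids, task, ns, case, config, fold):
    cols = list(case.indices)
    train_stack = np.concatenate([f.features[:, cols] for f in train], axis=0)
    scaler = fit_scaler(train_stack)
    spec = NetSpec(task=task, ns=ns, n_channels=len(cols))
    fold_cfg = TrainConfig(
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        epochs=config.epochs, steps_per_epoch=config.steps_per_epoch,
        seed=int(np.random.SeedSequence([config.seed, fold]).generate_state(1)[0]
                 & 0x7FFFFFFF),
    )
    model = train_net(spec, train, fold_cfg, scaler,
                      forbidden_ids=test_ids, channel_indices=cols)
    y_true, y_pred = [], []
    for f in test:
        if len(f.features) < ns:
            continue
        pred = _predict_windows_cnn(model, f, cols)
        label = f.exercise.index if task == "exercise" else int(f.correct)
        y_true.extend([label] * len(pred))
        y_pred.extend(pred.tolist())
    return np.array(y_true), np.array(y_pred)


def _run_fold_tree(train, test, ns, case, kernel, seed):
    # the tree sees only (s_acc, s_flex); ablation drops a criterion when
    # its source channels are removed
    keep = [i for i, (name, chans) in enumerate(
        (("s_acc", ("ax", "ay", "az")), ("s_flex", ("f1", "f2"))))
        if all(c in case.retained for c in chans)]
    if not keep:
        raise ValueError(f"ablation {case.name!r} leaves the tree no features")

    def collect(files, overlapping):
        xs, ys = [], []
        for f in files:
            crit, _, correct = compute_fragment_criteria(
                f, ns, overlapping=overlapping, kernel=kernel)
            if len(crit):
                xs.append(crit[:, keep])
                ys.append(np.full(len(crit), int(correct)))
        return np.concatenate(xs), np.concatenate(ys)

    X_train, y_train = collect(train, overlapping=False)
    X_test, y_test = collect(test, overlapping=True)
    model = train_tree(X_train, y_train, seed=seed)
    return y_test, tree_predict(model, X_test)


def report_markdown(reports: Sequence[EvalReport]) -> str:
    """Human-readable summary table (mean (std) per metric and row)."""
    lines = ["| scheme | model | task | Ns | ablation | " +
             " | ".join(METRIC_NAMES) + " |",
             "|" + "---|" * (5 + len(METRIC_NAMES))]
    for r in reports:
        agg = r.aggregate()
        cells = [f"{agg[m][0]:.3f} ({agg[m][1]:.3f})" for m in METRIC_NAMES]
        lines.append(f"| {r.scheme} | {r.model_kind} | {r.task} | {r.ns} "
                     f"| {r.ablation} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
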