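"""Split plans, ablation, metrics against brute-force oracles, reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fleximu.classifiers import LeakageError, TrainConfig
from fleximu.evaluate import (
    ABLATION_CASES,
    EvalReport,
    SplitPlan,
    apply_ablation,
    classification_metrics,
    confusion,
    plan_five_fold,
    plan_loso,
    report_markdown,
    run_experiment,
)
from fleximu.features import CHANNELS


def _oracle_binary(y_true, y_pred):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    acc = (tp + tn) / len(y_true)
    return prec, rec, f1, acc


def _oracle_weighted(y_true, y_pred, k=6):
    precs, recs, f1s, supports = [], [], [], []
    for c in range(k):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precs.append(p); recs.append(r); f1s.append(f)
        supports.append(int(np.sum(y_true == c)))
    w = np.array(supports) / max(1, sum(supports))
    return (float(w @ precs), float(w @ recs), float(w @ f1s),
            float(np.mean(y_true == y_pred)))


class TestSplitPlans:
    def test_five_fold_partitions_files(self):
        ids = [f"f{i}" for i in range(292)]
        plan = plan_five_fold(ids, seed=0)
        sizes = sorted(len(test) for _, test in plan.folds)
        assert sizes == [58, 58, 58, 59, 59]
        all_test = [i for _, test in plan.folds for i in test]
        assert sorted(all_test) == list(range(292))
        for train, test in plan.folds:
            assert not set(train) & set(test)

    def test_five_fold_deterministic_in_seed(self):
        ids = [f"f{i}" for i in range(40)]
        assert plan_five_fold(ids, 7).folds == plan_five_fold(ids, 7).folds
        assert plan_five_fold(ids, 7).folds != plan_five_fold(ids, 8).folds

    def test_five_fold_needs_five_files(self):
        with pytest.raises(ValueError, match="at least 5"):
            plan_five_fold(["a", "b"], 0)

    def test_loso_one_fold_per_subject_sorted(self):
        subjects = ["s2", "s1", "s2", "s3", "s1", "s3"]
        plan = plan_loso(subjects)
        assert len(plan) == 3
        test_subjects = [{subjects[i] for i in test} for _, test in plan.folds]
        assert test_subjects == [{"s1"}, {"s2"}, {"s3"}]
        for train, test in plan.folds:
            assert not {subjects[i] for i in train} & {subjects[i] for i in test}

    def test_loso_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            plan_loso(["s1", "s1"])

    def test_overlapping_fold_rejected(self):
        with pytest.raises(LeakageError):
            SplitPlan(scheme="five_fold", folds=(((0, 1), (1, 2)),))


class TestAblation:
    @pytest.mark.parametrize("case,n_cols", [
        ("normal", 10), ("noflex", 8), ("nogyro", 7),
        ("noaccel", 7), ("noangles", 8), ("noimu", 2),
    ])
    def test_retained_column_counts(self, case, n_cols):
        M = np.arange(21 * 10, dtype=float).reshape(21, 10)
        out = apply_ablation(M, case)
        assert out.shape == (21, n_cols)

    def test_normal_is_identity(self):
        M = np.random.default_rng(0).normal(size=(5, 10))
        np.testing.assert_array_equal(apply_ablation(M, "normal"), M)

    def test_noimu_keeps_only_flex(self):
        M = np.arange(10, dtype=float)[None, :]
        out = apply_ablation(M, "noimu")
        assert [CHANNELS[i] for i in ABLATION_CASES["noimu"].indices] == ["f1", "f2"]
        np.testing.assert_array_equal(out, [[3.0, 4.0]])

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            apply_ablation(np.zeros((5, 10)), "nofun")


class TestMetrics:
    def test_hand_computed_binary_example(self):
        # TP=9, FP=1, FN=3, TN=7
        y_true = np.r_[np.ones(12), np.zeros(8)].astype(int)
        y_pred = np.r_[np.ones(9), np.zeros(3), np.ones(1), np.zeros(7)].astype(int)
        m = classification_metrics(y_pred, y_true, "anomaly")
        assert m["precision"] == pytest.approx(0.9)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.8182, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 4, 5, 1, 2])
        m = classification_metrics(y, y, "exercise")
        assert all(v == 1.0 for v in m.values())

    def test_weighted_equals_plain_average_when_balanced(self):
        # equal supports make the support-weighted average collapse to the
        # unweighted mean of the per-class scores
        from sklearn.metrics import precision_recall_fscore_support

        y_true = np.repeat(np.arange(3), 10)
        y_pred = np.random.default_rng(0).integers(0, 3, 30)
        m = classification_metrics(y_pred, y_true, "exercise")
        macro = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0)
        assert m["precision"] == pytest.approx(macro[0])
        assert m["recall"] == pytest.approx(macro[1])
        assert m["f1"] == pytest.approx(macro[2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            classification_metrics([], [], "anomaly")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), task=st.sampled_from(["anomaly", "exercise"]))
    def test_agrees_with_bruteforce_oracle(self, seed, task):
        rng = np.random.default_rng(seed)
        k = 2 if task == "anomaly" else 6
        y_true = rng.integers(0, k, 60)
        y_pred = rng.integers(0, k, 60)
        if task == "anomaly" and len(np.unique(y_true)) < 2:
            return
        m = classification_metrics(y_pred, y_true, task)
        oracle = (_oracle_binary if task == "anomaly" else _oracle_weighted)(
            y_true, y_pred)
        for got, want in zip((m["precision"], m["recall"], m["f1"],
                              m["accuracy"]), oracle):
            assert got == pytest.approx(want, abs=1e-12)


class TestConfusion:
    def test_perfect_predictions_identity(self):
        y = np.tile(np.arange(6), 4)
        np.testing.assert_array_equal(confusion(y, y), np.eye(6))

    def test_rows_sum_to_one_when_supported(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 6, 300)
        y_pred = rng.integers(0, 6, 300)
        cm = confusion(y_pred, y_true)
        np.testing.assert_allclose(cm.sum(axis=1), 1.0, atol=1e-9)

    def test_hand_computed_two_class_row(self):
        y_true = np.array([0, 0, 0, 0, 1])
        y_pred = np.array([0, 0, 0, 1, 1])
        cm = confusion(y_pred, y_true, n_classes=2)
        np.testing.assert_allclose(cm[0], [0.75, 0.25])

    def test_zero_support_row_warns_and_is_zero(self):
        with pytest.warns(UserWarning, match="zero support"):
            cm = confusion(np.array([0, 1]), np.array([0, 1]), n_classes=3)
        np.testing.assert_array_equal(cm[2], 0.0)


class TestEvalReport:
    def test_aggregate_mean_and_sample_std(self):
        fm = [{"precision": p, "recall": p, "f1": p, "accuracy": p}
              for p in (0.8, 0.9, 1.0)]
        r = EvalReport(scheme="five_fold", model_kind="cnn", task="exercise",
                       ns=21, ablation="normal", fold_metrics=fm)
        mean, std = r.aggregate()["accuracy"]
        assert mean == pytest.approx(0.9)
        assert std == pytest.approx(np.std([0.8, 0.9, 1.0], ddof=1))

    def test_markdown_contains_rows(self):
        fm = [{"precision": 1.0, "recall": 1.0, "f1": 1.0, "accuracy": 1.0}]
        r = EvalReport(scheme="loso", model_kind="tree", task="anomaly",
                       ns=42, ablation="noflex", fold_metrics=fm)
        md = report_markdown([r])
        assert "| loso | tree | anomaly | 42 | noflex |" in md


class TestRunExperiment:
    def test_report_structure_five_fold(self, small_files, small_dataset):
        _, manifest = small_dataset
        plan = plan_five_fold(manifest["file_id"].tolist(), seed=0)
        cfg = TrainConfig(epochs=1, steps_per_epoch=5, seed=0)
        r = run_experiment(small_files, "cnn", "exercise", 21, "normal",
                           plan, cfg)
        assert len(r.fold_metrics) == 5
        assert r.confusion_matrix.shape == (6, 6)
        assert all(0 <= fm[m] <= 1 for fm in r.fold_metrics for m in fm)

    def test_tree_requires_anomaly_task(self, small_files, small_dataset):
        _, manifest = small_dataset
        plan = plan_five_fold(manifest["file_id"].tolist(), seed=0)
        with pytest.raises(ValueError, match="anomaly"):
            run_experiment(small_files, "tree", "exercise", 21, "normal", plan)

    def test_tree_ignores_ablations_outside_its_features(self, small_files,
                                                         small_dataset):
        _, manifest = small_dataset
        plan = plan_five_fold(manifest["file_id"].tolist(), seed=0)
        cfg = TrainConfig(seed=0)
        base = run_experiment(small_files, "tree", "anomaly", 21, "normal",
                              plan, cfg)
        noang = run_experiment(small_files, "tree", "anomaly", 21, "noangles",
                               plan, cfg)
        assert base.fold_metrics == noang.fold_metrics

    def test_tree_with_no_criteria_left_rejected(self, small_files,
                                                 small_dataset):
        _, manifest = small_dataset
        plan = plan_five_fold(manifest["file_id"].tolist(), seed=0)
        case = ABLATION_CASES["noimu"]  # drops accel; tree keeps s_flex only
        r = run_experiment(small_files, "tree", "anomaly", 21, case, plan,
                           TrainConfig(seed=0))
        assert len(r.fold_metrics) == 5  # s_flex alone still works
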