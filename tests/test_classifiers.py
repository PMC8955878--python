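"""Fragmenting, the two-criteria tree, and the CNN training contracts."""

import numpy as np
import pytest

from fleximu.classifiers import (
    FileFeatures,
    LeakageError,
    NetSpec,
    TrainConfig,
    TwoCriteria,
    binarize_anomaly_score,
    build_net,
    compute_fragment_criteria,
    featurize_session,
    load_model,
    predict_anomaly,
    predict_exercise,
    save_model,
    train_net,
    train_tree,
    tree_predict,
)
from fleximu.features import fit_scaler, extract_windows, apply_scaler
from fleximu.sensor_model import ExerciseLabel


def _toy_files(n_per_class=3, n=200, ns=21, classes=(0, 1), seed=0):
    """Synthetic FileFeatures: class k oscillates with amplitude k+1."""
    rng = np.random.default_rng(seed)
    files = []
    t = np.arange(n)
    for c in classes:
        for j in range(n_per_class):
            amp = 0.2 + 2.0 * c
            X = amp * np.sin(2 * np.pi * 0.05 * t[:, None] + rng.uniform(0, 6))
            X = np.repeat(X, 10, axis=1) + rng.normal(0, 0.05, (n, 10))
            files.append(FileFeatures(
                file_id=f"f{c}_{j}", subject_id="s01",
                exercise=list(ExerciseLabel)[c], correct=bool(c),
                fs=21.0, features=X))
    return files


class TestFragmenting:
    def test_fragment_counts(self, correct_session):
        s = correct_session  # 630 samples
        non_overlap, _, _ = compute_fragment_criteria(s, 21, overlapping=False)
        overlap, _, _ = compute_fragment_criteria(s, 21, overlapping=True)
        assert len(non_overlap) == len(s) // 21
        assert len(overlap) == len(s) - 21 + 1

    def test_single_window_boundary(self, correct_session):
        f = featurize_session(correct_session, "x")
        f.accel, f.flex_sum = f.accel[:21], f.flex_sum[:21]
        for overlapping in (False, True):
            crit, _, _ = compute_fragment_criteria(f, 21, overlapping)
            assert len(crit) == 1

    def test_short_file_warns_and_is_empty(self, correct_session):
        f = featurize_session(correct_session, "x")
        f.accel, f.flex_sum = f.accel[:10], f.flex_sum[:10]
        with pytest.warns(UserWarning, match="shorter"):
            crit, _, _ = compute_fragment_criteria(f, 21, False)
        assert len(crit) == 0

    def test_criteria_match_scalar_oracles(self, correct_session):
        from fleximu.features import s_acc, s_flex

        crit, _, _ = compute_fragment_criteria(correct_session, 21, True)
        acc, fx = correct_session.accel, correct_session.flex.sum(axis=1)
        for i in (0, 17, 100, len(crit) - 1):
            assert crit[i, 0] == pytest.approx(s_acc(acc[i:i + 21]), rel=1e-12)
            assert crit[i, 1] == pytest.approx(s_flex(fx[i:i + 21]), rel=1e-12)


class TestTree:
    def test_separable_data_perfect_at_depth_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([np.column_stack([rng.uniform(10, 20, 50), rng.uniform(0, 1, 50)]),
                       np.column_stack([rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)])])
        y = np.r_[np.ones(50), np.zeros(50)]
        model = train_tree(X, y, seed=0)
        assert model.depth <= 3
        assert (tree_predict(model, X) == y).all()

    def test_depth_never_exceeds_three(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 2)) ** 2
        y = rng.integers(0, 2, 500)
        assert train_tree(X, y, seed=1).depth <= 3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_tree(np.zeros((10, 2)), np.ones(10))

    def test_identical_features_mixed_labels_majority(self):
        X = np.ones((10, 2))
        y = np.r_[np.ones(7), np.zeros(3)]
        model = train_tree(X, y, seed=0)
        assert tree_predict(model, TwoCriteria(1.0, 1.0)) == 1

    def test_threshold_ties_go_left(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [10.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        model = train_tree(X, y, seed=0)
        thr = model.clf.tree_.threshold[0]
        at = tree_predict(model, np.array([thr, 0.0]))
        below = tree_predict(model, np.array([thr - 1e-9, 0.0]))
        assert at == below  # <= goes to the left branch

    def test_manual_traversal_of_toy_tree(self):
        X = np.array([[0.0, 0.0], [0.0, 5.0], [8.0, 0.0], [8.0, 5.0]] * 5)
        y = np.array([0, 1, 1, 1] * 5)
        model = train_tree(X, y, seed=0)
        tree = model.clf.tree_
        for x in X:
            node = 0
            while tree.children_left[node] != -1:
                f, t = tree.feature[node], tree.threshold[node]
                node = (tree.children_left[node] if x[f] <= t
                        else tree.children_right[node])
            manual = int(np.argmax(tree.value[node]))
            assert tree_predict(model, x) == model.clf.classes_[manual]

    def test_negative_criteria_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            TwoCriteria(-1.0, 0.0)


class TestNetSpec:
    def test_parameter_budget_respected(self):
        for task in ("exercise", "anomaly"):
            for ns in (10, 21, 42):
                spec = NetSpec(task=task, ns=ns)
                assert spec.param_count <= 5000

    def test_param_count_matches_built_network(self):
        m = build_net("exercise", 21)
        assert m.net.param_count == m.spec.param_count

    def test_exercise_head_probabilities(self):
        m = build_net("exercise", 21, seed=0)
        X = np.random.default_rng(0).normal(size=(4, 21, 10))
        p = predict_exercise(m, X)
        assert p.shape == (4, 6)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_anomaly_head_scalar_range(self):
        m = build_net("anomaly", 21, seed=0)
        score = predict_anomaly(m, np.random.default_rng(0).normal(size=(21, 10)))
        assert 0.0 < score < 1.0

    def test_shape_mismatch_rejected(self):
        m = build_net("exercise", 21)
        with pytest.raises(ValueError, match="shape"):
            predict_exercise(m, np.zeros((10, 10)))


class TestTraining:
    def test_separable_anomaly_data_learned_quickly(self):
        files = _toy_files()
        scaler = fit_scaler(np.concatenate([f.features for f in files]))
        spec = NetSpec(task="anomaly", ns=21)
        model = train_net(spec, files, TrainConfig(epochs=10, steps_per_epoch=30,
                                                   seed=0), scaler)
        correct = total = 0
        for f in files:
            wins = apply_scaler(extract_windows(f.features, 21, 3), scaler)
            pred = binarize_anomaly_score(model.net.predict(wins)[:, 0])
            correct += (pred == int(f.correct)).sum()
            total += len(pred)
        assert correct / total >= 0.95

    def test_equal_seeds_identical_loss_traces(self):
        files = _toy_files()
        scaler = fit_scaler(np.concatenate([f.features for f in files]))
        spec = NetSpec(task="anomaly", ns=21)
        cfg = TrainConfig(epochs=2, steps_per_epoch=10, seed=42)
        m1 = train_net(spec, files, cfg, scaler)
        m2 = train_net(spec, files, cfg, scaler)
        assert m1.loss_trace == m2.loss_trace

    def test_leakage_guard(self):
        files = _toy_files()
        scaler = fit_scaler(np.concatenate([f.features for f in files]))
        with pytest.raises(LeakageError, match="f1_0"):
            train_net(NetSpec(task="anomaly", ns=21), files,
                      TrainConfig(epochs=1, steps_per_epoch=1, seed=0),
                      scaler, forbidden_ids={"f1_0"})

    def test_warm_start_reaches_cold_start_loss(self, small_files):
        # median over 5 seeds: warm-started anomaly training ends at a loss
        # no worse than cold start with the same step budget
        train = small_files
        scaler = fit_scaler(np.concatenate([f.features for f in train]))
        deltas = []
        for seed in range(5):
            ex = train_net(NetSpec(task="exercise", ns=21),
                           [f for f in train if f.correct],
                           TrainConfig(epochs=3, steps_per_epoch=40, seed=seed),
                           scaler)
            cfg = TrainConfig(epochs=3, steps_per_epoch=40, seed=seed + 100)
            spec = NetSpec(task="anomaly", ns=21)
            cold = train_net(spec, train, cfg, scaler)
            warm = train_net(spec, train, cfg, scaler, init_from=ex)
            deltas.append(cold.loss_trace[-1] - warm.loss_trace[-1])
        assert np.median(deltas) >= 0.0

    def test_overfit_single_files_recovers_classes(self):
        files = _toy_files(n_per_class=1, classes=(0, 1, 2), seed=3)
        scaler = fit_scaler(np.concatenate([f.features for f in files]))
        model = train_net(NetSpec(task="exercise", ns=21), files,
                          TrainConfig(epochs=10, steps_per_epoch=30, seed=0),
                          scaler)
        for f in files:
            wins = apply_scaler(extract_windows(f.features, 21, 5), scaler)
            pred = model.net.predict(wins).argmax(axis=1)
            # majority of windows from a memorized file recover its class
            assert np.bincount(pred, minlength=6).argmax() == f.exercise.index


class TestBinarize:
    @pytest.mark.parametrize("score,expected", [(0.7, 1), (0.5, 1), (0.49, 0)])
    def test_threshold_and_ties(self, score, expected):
        assert binarize_anomaly_score(score) == expected


class TestModelBundle:
    def test_save_load_roundtrip(self, tmp_path):
        files = _toy_files()
        scaler = fit_scaler(np.concatenate([f.features for f in files]))
        model = train_net(NetSpec(task="anomaly", ns=21), files,
                          TrainConfig(epochs=1, steps_per_epoch=5, seed=0), scaler)
        save_model(model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        X = np.random.default_rng(0).normal(size=(3, 21, 10))
        np.testing.assert_array_equal(loaded.net.predict(X), model.net.predict(X))
        assert loaded.label_order == model.label_order
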