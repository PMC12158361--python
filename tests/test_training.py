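"""Training schedule, metrics, cross-validation, and the sklearn estimator."""

import numpy as np
import pytest

import semgimg as sg
from semgimg.training import compute_report
from semgimg.windows import ConfigurationError


@pytest.fixture(scope="module")
def tiny_model(small_datasets_module):
    train_ds, test_ds = small_datasets_module
    spec = sg.sscnn_spec("sigimg", train_ds.class_count, tw=20, channels=10,
                         width_scale=0.25, fc_sizes=(64, 32))
    config = sg.TrainConfig(batch_size=50, epochs=3, lr_initial=0.001,
                            seed=2)
    model, history = sg.train(spec, train_ds, config)
    return model, history, train_ds, test_ds


@pytest.fixture(scope="module")
def small_datasets_module():
    cfg = sg.SynthConfig(subjects=2, gestures=3, repetitions=10,
                         channels=10, fs=100.0, duration_s=1.0,
                         snr_db=10.0, seed=11)
    return sg.build_dataset(sg.generate(cfg), sg.WindowSpec(200, 400))


class TestSchedule:
    def test_reference_learning_rate_decay(self):
        cfg = sg.TrainConfig()
        assert (cfg.batch_size, cfg.epochs, cfg.lr_initial) == (100, 30, 0.1)
        assert sg.learning_rate(cfg, 1) == 0.1
        assert sg.learning_rate(cfg, 15) == 0.1
        assert sg.learning_rate(cfg, 16) == pytest.approx(0.01)
        assert sg.learning_rate(cfg, 23) == pytest.approx(0.01)
        assert sg.learning_rate(cfg, 24) == pytest.approx(0.001)
        assert sg.learning_rate(cfg, 30) == pytest.approx(0.001)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            sg.TrainConfig(batch_size=0)
        with pytest.raises(ConfigurationError):
            sg.TrainConfig(dropout=1.0)

    def test_history_one_entry_per_epoch(self, tiny_model):
        _, history, _, _ = tiny_model
        assert [h["epoch"] for h in history] == [1, 2, 3]
        assert all(np.isfinite(h["loss"]) for h in history)

    def test_seed_reproducible(self, small_datasets_module):
        train_ds, _ = small_datasets_module
        spec = sg.sscnn_spec("sigimg", train_ds.class_count, width_scale=0.25,
                             fc_sizes=(32, 16))
        cfg = sg.TrainConfig(batch_size=50, epochs=2, lr_initial=0.001, seed=9)
        _, h1 = sg.train(spec, train_ds, cfg)
        _, h2 = sg.train(spec, train_ds, cfg)
        assert h1 == h2

    def test_shape_mismatch_fails_before_training(self, small_datasets_module):
        train_ds, _ = small_datasets_module
        spec = sg.sscnn_spec("sigimg", train_ds.class_count, tw=10, channels=4)
        with pytest.raises(ConfigurationError):
            sg.train(spec, train_ds, sg.TrainConfig(epochs=1))


class TestEvalReport:
    def test_all_correct(self):
        y = np.array([0, 1, 2, 1])
        rep = compute_report(y, y, np.array([1, 1, 2, 2]), 3)
        assert rep.mean_accuracy == 1.0
        assert set(rep.per_subject_accuracy.values()) == {1.0}
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_precision_recall_hand_example(self):
        # one-vs-rest for class 1: TP=3, FP=1, FN=2
        y_true = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0])
        rep = compute_report(y_true, y_pred, np.ones(9), 2)
        from sklearn.metrics import precision_score, recall_score
        assert precision_score(y_true, y_pred) == pytest.approx(0.75)
        assert recall_score(y_true, y_pred) == pytest.approx(0.6)
        # macro averages include class 0 (precision 3/5, recall 3/4) as well
        assert rep.precision == pytest.approx((0.75 + 0.6) / 2)
        assert rep.recall == pytest.approx((0.6 + 0.75) / 2)

    def test_confusion_matrix_totals(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 60)
        y_pred = rng.integers(0, 4, 60)
        rep = compute_report(y_true, y_pred, np.ones(60), 4)
        assert rep.confusion_matrix.sum() == 60
        np.testing.assert_array_equal(
            rep.confusion_matrix.sum(axis=1),
            np.bincount(y_true, minlength=4),
        )
        np.testing.assert_array_equal(
            rep.confusion_matrix.sum(axis=0),
            np.bincount(y_pred, minlength=4),
        )

    def test_mean_accuracy_invariant_to_subject_order(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 40)
        y_pred = rng.integers(0, 3, 40)
        subjects = rng.integers(1, 5, 40)
        r1 = compute_report(y_true, y_pred, subjects, 3)
        perm = rng.permutation(40)
        r2 = compute_report(y_true[perm], y_pred[perm], subjects[perm], 3)
        assert r1.mean_accuracy == pytest.approx(r2.mean_accuracy)
        assert r1.per_subject_accuracy == r2.per_subject_accuracy

    def test_per_subject_accuracy_is_correct_over_total(self, tiny_model):
        model, _, _, test_ds = tiny_model
        rep = sg.evaluate(model, test_ds)
        y_pred = model.predict(test_ds)
        for s, acc in rep.per_subject_accuracy.items():
            mask = test_ds.subjects == s
            assert acc == pytest.approx(
                (y_pred[mask] == test_ds.labels[mask]).mean())
        assert rep.mean_accuracy == pytest.approx(
            np.mean(list(rep.per_subject_accuracy.values())))


class _ConstantModel:
    def __init__(self, label=0):
        self.label = label

    def predict(self, dataset):
        return np.full(len(dataset), self.label)


class TestCrossValidate:
    def test_partition_property_and_determinism(self, small_datasets_module):
        train_ds, _ = small_datasets_module
        seen = []

        class Recorder(_ConstantModel):
            def predict(self, dataset):
                seen.append(dataset.start_indices.copy())
                return super().predict(dataset)

        out1 = sg.cross_validate(train_ds, trainer=lambda ds: Recorder(),
                                 config=sg.TrainConfig(seed=4), folds=5,
                                 repeats=2)
        total = sum(len(s) for s in seen)
        assert total == 2 * len(train_ds)  # each sample tested once per repeat
        out2 = sg.cross_validate(train_ds, trainer=lambda ds: _ConstantModel(),
                                 config=sg.TrainConfig(seed=4), folds=5,
                                 repeats=2)
        assert out1["per_repeat"] == out2["per_repeat"]

    def test_constant_model_scores_chance(self, small_datasets_module):
        train_ds, _ = small_datasets_module
        out = sg.cross_validate(train_ds, trainer=lambda ds: _ConstantModel(0),
                                config=sg.TrainConfig(seed=0), folds=5,
                                repeats=3)
        # balanced 3-class data: a constant prediction scores ~1/3
        assert out["mean_accuracy"] == pytest.approx(1 / 3, abs=0.05)
        assert out["stratified"] is True

    def test_downgrade_to_plain_kfold(self):
        cfg = sg.SynthConfig(subjects=1, gestures=3, repetitions=10,
                             duration_s=0.6, seed=2)
        train_ds, _ = sg.build_dataset(sg.generate(cfg),
                                       sg.WindowSpec(200, 400))
        # keep 3 samples of one class so stratification is impossible
        keep = np.r_[np.flatnonzero(train_ds.labels == 0)[:3],
                     np.flatnonzero(train_ds.labels != 0)]
        small = train_ds.subset(keep)
        with pytest.warns(UserWarning, match="non-stratified"):
            out = sg.cross_validate(small, trainer=lambda ds: _ConstantModel(),
                                    folds=5, repeats=1)
        assert out["stratified"] is False


class TestSklearnEstimator:
    def test_fit_predict_on_encoded_features(self, rng):
        # two well-separated synthetic classes at a tiny geometry
        tw, C = 8, 3
        n = 40
        X_raw = rng.random((n, tw, C))
        y = np.repeat([0, 1], n // 2)
        X_raw[y == 1, :, 0] += 2.0  # class-dependent channel activation
        enc = sg.WindowImageEncoder(q=4).fit(X_raw)
        X = enc.transform(X_raw)
        clf = sg.MultiStreamCNNClassifier(
            arch="sscnn", streams=("sigimg",), tw=tw, channels=C,
            width_scale=0.25, fc_sizes=(16, 8), epochs=15, batch_size=10,
            lr=0.003, dropout=0.1, random_state=0)
        clf.fit(X, y)
        assert clf.model_ is not None
        assert list(clf.classes_) == [0, 1]
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert clf.score(X, y) > 0.8

    def test_get_set_params_round_trip(self):
        clf = sg.MultiStreamCNNClassifier(epochs=5)
        params = clf.get_params()
        assert params["epochs"] == 5 and params["arch"] == "mscnn"
        clf.set_params(arch="dscnn", streams=("gadf", "mtf"))
        assert clf.arch == "dscnn"

    def test_wrong_feature_width_rejected(self, rng):
        clf = sg.MultiStreamCNNClassifier(tw=8, channels=3, epochs=1)
        with pytest.raises(ValueError):
            clf.fit(rng.random((10, 50)), np.repeat([0, 1], 5))
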