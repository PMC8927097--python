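"""Balancing rule, MLP training contracts, cube prediction, auxiliary classifiers."""

import time

import numpy as np
import pytest

from spectropath.annotation import (BACKGROUND, CLASSES_3, SQUAMOUS, TUMOR,
                                    UNCLASSIFIED, merge_classes)
from spectropath.cube_io import Hypercube, WavelengthGrid
from spectropath.errors import ConfigurationError, TrainingError, ValidationError
from spectropath.features import HSI_FEATURES, extract_features
from spectropath.model import (AuxClassifierSpec, MLPConfig, balance,
                               load_model, predict_map, save_model, train_aux,
                               train_mlp)


def labels_from_counts(counts):
    return np.array(sum(([lab] * n for lab, n in counts.items()), []), dtype=object)


class TestBalance:
    def test_rule_application(self):
        labels = labels_from_counts({"eac": 100, "stroma": 50,
                                     "background": 30, "squamous": 20})
        idx = balance(labels, rng_seed=0)
        kept = labels[idx]
        counts = {lab: int((kept == lab).sum()) for lab in set(kept.tolist())}
        assert counts == {"eac": 20, "stroma": 20, "background": 20, "squamous": 20}

    def test_equal_counts_identity(self):
        labels = labels_from_counts({"eac": 10, "stroma": 10,
                                     "background": 10, "squamous": 10})
        assert balance(labels, rng_seed=0).tolist() == list(range(40))

    def test_seed_determinism(self):
        labels = labels_from_counts({"eac": 50, "squamous": 10})
        assert balance(labels, 7).tolist() == balance(labels, 7).tolist()
        assert balance(labels, 7).tolist() != balance(labels, 8).tolist()

    def test_small_class_kept_whole_with_warning(self):
        labels = labels_from_counts({"eac": 5, "squamous": 10})
        with pytest.warns(UserWarning, match="kept whole"):
            idx = balance(labels, rng_seed=0)
        assert len(idx) == 15

    def test_no_label_changes(self):
        labels = labels_from_counts({"eac": 30, "stroma": 25,
                                     "background": 22, "squamous": 20})
        idx = balance(labels, rng_seed=3)
        assert set(labels[idx].tolist()) == set(labels.tolist())

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            balance(labels_from_counts({"eac": 5}), rng_seed=0)


def separable_toy(n=200, margin=1.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    xa = rng.normal([-margin, 0.0], 0.2, size=(half, 2))
    xb = rng.normal([+margin, 0.0], 0.2, size=(half, 2))
    X = np.vstack([xa, xb])
    y = np.array(["a"] * half + ["b"] * half, dtype=object)
    return X, y


class TestTrainMLP:
    def test_separable_toy_learned(self):
        X, y = separable_toy()
        model = train_mlp(X, y, MLPConfig(input_dim=2, rng_seed=0))
        acc = (model.predict_labels(X) == y).mean()
        assert acc >= 0.99

    def test_no_signal_gives_chance(self):
        rng = np.random.default_rng(0)
        X = np.zeros((400, 2)) + rng.normal(0, 1e-9, (400, 2))
        y = np.array(["a", "b"] * 200, dtype=object)
        model = train_mlp(X[:300], y[:300], MLPConfig(input_dim=2, rng_seed=0))
        acc = (model.predict_labels(X[300:]) == y[300:]).mean()
        assert 0.3 <= acc <= 0.7

    def test_same_data_and_seed_identical_predictions(self):
        X, y = separable_toy(seed=2)
        m1 = train_mlp(X, y, MLPConfig(input_dim=2, rng_seed=5))
        m2 = train_mlp(X, y, MLPConfig(input_dim=2, rng_seed=5))
        np.testing.assert_array_equal(m1.predict_scores(X), m2.predict_scores(X))

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(TrainingError):
            train_mlp(X, np.array(["a"] * 10), MLPConfig(input_dim=2))

    def test_nan_features_rejected(self):
        X, y = separable_toy(n=20)
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            train_mlp(X, y, MLPConfig(input_dim=2))

    def test_architecture_is_fixed(self):
        with pytest.raises(ConfigurationError):
            MLPConfig(hidden_sizes=(32, 16, 8))
        with pytest.raises(ConfigurationError):
            MLPConfig(activation="relu")

    def test_manifest_records_training(self):
        X, y = separable_toy()
        model = train_mlp(X, y, MLPConfig(input_dim=2, rng_seed=0))
        assert model.manifest["class_counts"] == {"a": 100, "b": 100}
        assert model.manifest["config"]["rng_seed"] == 0

    def test_scores_lie_on_simplex(self):
        X, y = separable_toy()
        model = train_mlp(X, y, MLPConfig(input_dim=2, rng_seed=0))
        scores = model.predict_scores(X)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(scores >= 0)


@pytest.fixture(scope="module")
def cohort_model(small_table):
    """MLP trained on the small cohort's balanced merged feature table."""
    df = extract_features(small_table)
    idx = balance(df["label"].to_numpy(), rng_seed=0)
    merged = np.array([{"eac": TUMOR, "stroma": TUMOR}.get(l, l)
                       for l in df["label"].to_numpy()[idx]], dtype=object)
    X = df[list(HSI_FEATURES)].to_numpy()[idx]
    return train_mlp(X, merged, MLPConfig(rng_seed=0))


class TestPredictMap:
    def test_single_class_cube_classified_correctly(self, cohort_model, small_cohort):
        import dataclasses
        from spectropath.annotation import PatientRecord, SQUAMOUS
        from spectropath.synthetic import (PatientClassEffect, simulate_cube,
                                           default_class_models)
        cfg = dataclasses.replace(small_cohort.config, cube_height=24, cube_width=24)
        model_sq = default_class_models()[SQUAMOUS]
        cube, _ = simulate_cube(PatientRecord("PX"),
                                {SQUAMOUS: PatientClassEffect(
                                    model_sq.eosin_load.mean,
                                    model_sq.hematoxylin_load.mean)},
                                cfg, np.random.default_rng(0),
                                layout={SQUAMOUS: (0, 24, 0, 24)})
        labels, scores = predict_map(cohort_model, cube)
        assert labels.shape == (24, 24)
        assert (labels == SQUAMOUS).mean() >= 0.99

    def test_argmax_consistency_and_dims(self, cohort_model, small_cohort):
        cube = small_cohort.cubes[0]
        labels, scores = predict_map(cohort_model, cube)
        h, w, _ = cube.shape
        assert labels.shape == (h, w) and scores.shape == (h, w, 3)
        classified = labels != UNCLASSIFIED
        idx = np.argmax(scores, axis=2)
        expected = np.array(CLASSES_3, dtype=object)[idx]
        assert np.array_equal(labels[classified], expected[classified])

    def test_full_frame_throughput(self, cohort_model):
        """A full 640x480 specimen frame classifies in well under a minute."""
        cube = Hypercube(np.full((480, 640, 100), 0.5), WavelengthGrid())
        t0 = time.time()
        labels, _ = predict_map(cohort_model, cube)
        elapsed = time.time() - t0
        assert elapsed < 60.0
        assert labels.shape == (480, 640)

    def test_variant_mismatch_rejected(self, cohort_model, small_cohort):
        import dataclasses
        broken = dataclasses.replace(cohort_model, variant="rgb3")
        with pytest.raises(ConfigurationError):
            predict_map(broken, small_cohort.cubes[0])


class TestAuxClassifiers:
    def test_logistic_regression_on_separable_toy(self):
        X, y = separable_toy()
        aux = train_aux(AuxClassifierSpec("logistic-regression"), X, y)
        assert (aux.predict(X) == y).mean() >= 0.99

    def test_random_forest_seed_determinism(self):
        X, y = separable_toy(seed=4)
        a = train_aux(AuxClassifierSpec("random-forest", rng_seed=1), X, y)
        b = train_aux(AuxClassifierSpec("random-forest", rng_seed=1), X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_poly_svm_beats_logistic_regression_on_xor(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (400, 2))
        y = np.where(X[:, 0] * X[:, 1] > 0, "pos", "neg").astype(object)
        svm = train_aux(AuxClassifierSpec("support-vector-machine-poly-kernel",
                                          {"degree": 2, "coef0": 1.0}), X, y)
        lr = train_aux(AuxClassifierSpec("logistic-regression"), X, y)
        acc_svm = (svm.predict(X) == y).mean()
        acc_lr = (lr.predict(X) == y).mean()
        assert acc_svm > acc_lr

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            AuxClassifierSpec("gradient-boosting")

    def test_single_level_rejected(self):
        X, _ = separable_toy(n=10)
        with pytest.raises(TrainingError):
            train_aux(AuxClassifierSpec("logistic-regression"), X,
                      np.array(["x"] * 10))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = separable_toy()
        model = train_mlp(X, y, MLPConfig(input_dim=2, rng_seed=0))
        path = str(tmp_path / "model.joblib")
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict_scores(X), model.predict_scores(X))
        assert back.manifest == model.manifest
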