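"""Metric definitions, ROC-AUC pair semantics, LOPOCV integrity, TNM CV harness."""

import numpy as np
import pandas as pd
import pytest

from spectropath.annotation import CLASSES_3, PatientRecord
from spectropath.errors import ValidationError
from spectropath.evaluation import (ConfusionCounts, FoldReport, compare_auc,
                                    confusion, lopocv, metrics, roc_auc,
                                    tnm_grading_cv, weighted_accuracy)


def pair_count_auc(scores, truth):
    """O(n^2) Mann-Whitney oracle: wins + half-ties over all pos/neg pairs."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        counts = confusion(["tumor", "squamous", "background"],
                           ["tumor", "squamous", "background"])
        for cls in CLASSES_3:
            assert counts[cls].fp == 0 and counts[cls].fn == 0

    def test_hand_enumerated_case(self):
        truth = ["a", "a", "b", "b"]
        pred = ["a", "b", "b", "b"]
        counts = confusion(pred, truth, classes=("a", "b"))
        assert counts["a"] == ConfusionCounts(tp=1, fp=0, tn=2, fn=1)
        assert counts["b"] == ConfusionCounts(tp=2, fp=1, tn=1, fn=0)

    def test_totals_equal_across_classes(self, rng):
        truth = rng.choice(CLASSES_3, 50)
        pred = rng.choice(CLASSES_3, 50)
        counts = confusion(pred, truth)
        assert {c.total for c in counts.values()} == {50}

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValidationError):
            confusion([], [])
        with pytest.raises(ValidationError):
            confusion(["tumor"], ["tumor", "squamous"])


class TestMetrics:
    def test_hand_oracle(self):
        m = metrics(ConfusionCounts(tp=1, fp=0, tn=2, fn=1))
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(1.0)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_perfect_counts(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_zero_support_flagged_nan(self):
        m = metrics(ConfusionCounts(tp=0, fp=2, tn=8, fn=0))
        assert np.isnan(m["sensitivity"])
        assert np.isfinite(m["specificity"])

    def test_f1_between_min_and_max_of_precision_recall(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 30, 4)
            m = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            assert min(precision, recall) - 1e-12 <= m["f1"] <= max(precision, recall) + 1e-12


class TestRocAuc:
    def test_separated_scores(self):
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]),
                       np.array([True, True, False, False])) == 1.0

    def test_pure_ties(self):
        assert roc_auc(np.full(10, 0.5),
                       np.array([True] * 5 + [False] * 5)) == pytest.approx(0.5)

    def test_matches_pair_oracle(self, rng):
        scores = rng.choice(np.linspace(0, 1, 7), 20)  # discrete -> ties occur
        truth = rng.uniform(size=20) < 0.5
        truth[0], truth[1] = True, False  # both classes present
        assert roc_auc(scores, truth) == pytest.approx(
            pair_count_auc(scores, truth), abs=1e-12)

    def test_single_class_undefined(self):
        assert np.isnan(roc_auc(np.array([0.1, 0.2]), np.array([True, True])))


class TestWeightedAccuracy:
    def test_perfect(self):
        counts = {"a": ConfusionCounts(3, 0, 1, 0), "b": ConfusionCounts(1, 0, 3, 0)}
        assert weighted_accuracy(counts) == pytest.approx(1.0)

    def test_weighted_mean_of_recalls(self):
        counts = {"a": ConfusionCounts(tp=3, fp=1, tn=0, fn=0),
                  "b": ConfusionCounts(tp=0, fp=0, tn=3, fn=1)}
        assert weighted_accuracy(counts) == pytest.approx(0.75)

    def test_equals_pooled_accuracy(self, rng):
        truth = rng.choice(CLASSES_3, 60)
        pred = rng.choice(CLASSES_3, 60)
        counts = confusion(pred, truth)
        assert weighted_accuracy(counts) == pytest.approx((truth == pred).mean())

    def test_macro_mode_weights_classes_equally(self):
        counts = {"a": ConfusionCounts(tp=3, fp=1, tn=0, fn=0),
                  "b": ConfusionCounts(tp=0, fp=0, tn=3, fn=1)}
        assert weighted_accuracy(counts, mode="macro") == pytest.approx(0.5)

    def test_zero_supports_rejected(self):
        counts = {"a": ConfusionCounts(0, 2, 2, 0)}
        with pytest.raises(ValidationError):
            weighted_accuracy(counts)


def fold_with_auc(pid, aucs):
    per_class = {cls: {"sensitivity": 1.0, "specificity": 1.0, "accuracy": 1.0,
                       "f1": 1.0, "roc_auc": auc}
                 for cls, auc in zip(CLASSES_3, aucs)}
    return FoldReport(pid, per_class, 1.0, 1.0, True, 100)


class TestCompareAuc:
    def make_folds(self, offsets, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        folds_a, folds_b = [], []
        for i in range(5):
            base = 0.7 + 0.01 * i
            eps = rng.normal(0, jitter, 3) if jitter else np.zeros(3)
            folds_a.append(fold_with_auc(f"P{i}", [base + o + e for o, e in
                                                   zip(offsets, eps)]))
            folds_b.append(fold_with_auc(f"P{i}", [base] * 3))
        return folds_a, folds_b

    def test_identical_reports_degenerate(self):
        a, b = self.make_folds([0.0, 0.0, 0.0])
        res = compare_auc(a, b)
        assert (res["t"] == 0.0).all()
        assert (res["p"] == 1.0).all()
        assert res["degenerate"].all()
        assert not res["significant"].any()

    def test_consistent_shift_is_significant(self):
        a, b = self.make_folds([0.1, 0.1, 0.1], jitter=1e-3)
        res = compare_auc(a, b)
        assert (res["p"] < 0.05).all()
        assert res["significant"].all()

    def test_sign_flip_antisymmetry(self):
        a, b = self.make_folds([0.1, -0.05, 0.02], jitter=1e-2)
        t_ab = compare_auc(a, b)["t"]
        t_ba = compare_auc(b, a)["t"]
        np.testing.assert_allclose(t_ab, -t_ba, rtol=1e-9)

    def test_mismatched_patients_rejected(self):
        a, b = self.make_folds([0.1, 0.1, 0.1])
        with pytest.raises(ValidationError):
            compare_auc(a[:-1], b)


class TestLopocv:
    def test_fold_count_and_disjointness(self, small_table):
        report, folds = lopocv(small_table, "all-hsi")
        assert report.n_folds == len(small_table.patients) == len(folds)
        for f in folds:
            assert f.patient_id not in f.train_patients
            assert len(f.train_patients) == report.n_folds - 1

    def test_patient_without_pixels_skipped(self, small_cohort):
        from spectropath.annotation import extract_spectra
        from spectropath.cube_io import crop_spectral
        pid_drop = sorted(small_cohort.patients)[0]
        rois = [r for r in small_cohort.rois if r.patient_id != pid_drop]
        cubes = [crop_spectral(c, 500, 750) for c in small_cohort.cubes]
        table = extract_spectra(cubes, rois, small_cohort.patients)
        # the dropped patient has no rows at all -> simply not a fold
        report, folds = lopocv(table, "all-hsi")
        assert report.n_folds == len(small_cohort.patients) - 1
        assert pid_drop not in {f.patient_id for f in folds}

    def test_subgroup_arms_partition_patients(self, small_table):
        from spectropath.evaluation import select_arm
        ctx = select_arm(small_table, "ctx")
        noctx = select_arm(small_table, "no-ctx")
        assert len(ctx) + len(noctx) == len(small_table)
        treated = {p for p, r in small_table.patients.items() if r.neoadjuvant != "none"}
        assert set(ctx.patient_ids.tolist()) == treated

    def test_single_patient_arm_rejected(self, small_table):
        mask = small_table.patient_ids.astype(str) == sorted(small_table.patients)[0]
        with pytest.raises(ValidationError):
            lopocv(small_table.subset(mask), "all-hsi")

    def test_noise_free_separable_cohort_is_perfect(self):
        """Separability limit: zero pixel/patient variability and zero noise
        give every fold 100% accuracy."""
        import dataclasses
        from spectropath.annotation import extract_spectra
        from spectropath.cube_io import crop_spectral
        from spectropath.synthetic import (CohortConfig, default_class_models,
                                           simulate_cohort)
        models = {lab: dataclasses.replace(
            m,
            eosin_load=dataclasses.replace(m.eosin_load, patient_sd=0.0, pixel_sd=0.0),
            hematoxylin_load=dataclasses.replace(m.hematoxylin_load,
                                                 patient_sd=0.0, pixel_sd=0.0),
            noise_sd=0.0, noise_sd_nir=0.0)
            for lab, m in default_class_models().items()}
        cfg = CohortConfig(n_patients=4, cube_height=32, cube_width=32,
                           roi_radius=2.0, illumination_gain_sd=0.0,
                           tnm_hema_shift=0.0, class_models=models, rng_seed=0)
        cohort = simulate_cohort(cfg)
        table = extract_spectra([crop_spectral(c, 500, 750) for c in cohort.cubes],
                                cohort.rois, cohort.patients)
        report, _ = lopocv(table, "all-hsi")
        assert report.mean.loc["accuracy", "tumor"] == pytest.approx(1.0)
        assert report.fraction_correct == 1.0


def synthetic_level_features(n_patients=10, pixels=80, shift=2.0, seed=0,
                             informative=True, n_positive=None):
    """Pixel features whose mean moves with the patient's nodal category."""
    rng = np.random.default_rng(seed)
    rows, patients = [], {}
    for i in range(n_patients):
        pid = f"P{i:02d}"
        if n_positive is None:
            level = "N+" if i % 2 else "N0"
        else:
            level = "N+" if i < n_positive else "N0"
        patients[pid] = PatientRecord(pid, N=level)
        mu = shift * (level == "N+") if informative else 0.0
        feats = rng.normal(mu, 1.0, size=(pixels, 3))
        for row in feats:
            rows.append({"patient_id": pid, "f1": row[0], "f2": row[1], "f3": row[2]})
    return pd.DataFrame(rows), patients


class TestTnmGradingCv:
    def test_recoverable_signal_found(self):
        feats, patients = synthetic_level_features()
        res = tnm_grading_cv(feats, "N", patients, rng_seed=0)
        assert res.loc[res["best"], "mean_accuracy"].iloc[0] >= 0.9
        assert res.index.tolist() == ["logistic-regression",
                                      "support-vector-machine-poly-kernel",
                                      "random-forest", "multi-layer-perceptron"]

    def test_uninformative_labels_give_majority_rate(self):
        """Permutation-style null: with label-independent features the best a
        classifier can do is the majority-class rate.  A clear majority (32
        vs 8 patients) keeps that baseline unbiased under grouped splits."""
        feats, patients = synthetic_level_features(n_patients=40, pixels=30,
                                                   informative=False,
                                                   n_positive=8)
        res = tnm_grading_cv(feats, "N", patients, rng_seed=0)
        majority = 32 / 40
        acc = res["mean_accuracy"]
        se = res["sd_accuracy"] / np.sqrt(res["n_splits"])
        lr = "logistic-regression"
        assert abs(acc[lr] - majority) <= 3 * max(se[lr], 0.02)

    def test_single_level_rejected(self):
        feats, patients = synthetic_level_features(n_patients=4)
        same = {p: PatientRecord(p, N="N0") for p in patients}
        with pytest.raises(ValidationError):
            tnm_grading_cv(feats, "N", same, rng_seed=0)

    def test_single_patient_level_dropped_with_warning(self):
        feats, patients = synthetic_level_features(n_patients=5)
        # exactly one N+ patient among five -> level dropped, then < 2 levels
        recs = {p: PatientRecord(p, N="N+" if p == "P01" else "N0")
                for p in patients}
        with pytest.warns(UserWarning, match="single patient"):
            with pytest.raises(ValidationError):
                tnm_grading_cv(feats, "N", recs, rng_seed=0)

    def test_unknown_target_rejected(self):
        feats, patients = synthetic_level_features(n_patients=4)
        with pytest.raises(ValidationError):
            tnm_grading_cv(feats, "R", patients)
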