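"""Leave-one-patient-out evaluation, metrics, subgroup and TNM analyses.

Every metric is computed pixel-wise from one-vs-rest confusion counts per
class: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, F1 = 2TP/(2TP+FP+FN), plus a threshold-free ROC-AUC (the
Mann-Whitney probability that a random positive pixel outscores a random
negative one, ties counted 1/2).  Ratios with a zero denominator are
undefined: they are reported as NaN with a logged reason and excluded from
cohort means rather than silently zeroed.

A specimen counts as "correctly classified" when its weighted accuracy --
the support-weighted mean of per-class recall over the test pixel pool,
which equals plain pooled accuracy -- exceeds 60%.  A macro-average mode
(equal class weights, i.e. balanced accuracy) is available for sensitivity
analysis; under a truth-independent predictor its expectation is exactly
1/3 for three classes, which is the natural chance level.

The leave-one-patient-out cross-validation (LOPOCV) harness trains on all
patients of an arm but one, balances classes inside the training fold only,
merges EAC+stroma into the tumor class, and tests on the held-out patient's
annotated pixels.  Cohort aggregation weights patients equally
(mean +- SD across folds).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupShuffleSplit

from .annotation import CLASSES_3, SpectrumTable, merged_label
from .errors import ValidationError
from .features import HSI_FEATURES, RGB_FEATURES, extract_features
from .model import (AUX_SIMPLICITY_ORDER, AuxClassifierSpec, MLPConfig,
                    TrainedModel, balance, train_aux, train_mlp)
from .preprocess import PreprocessConfig

logger = logging.getLogger(__name__)

ARMS = ("all-hsi", "no-ctx", "ctx", "all-rgb")
CORRECT_THRESHOLD = 0.60
METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "f1", "roc_auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def support(self) -> int:
        return self.tp + self.fn


def confusion(pred: Sequence[str], truth: Sequence[str],
              classes: Sequence[str] = CLASSES_3) -> dict[str, ConfusionCounts]:
    pred = np.asarray(pred).astype(str)
    truth = np.asarray(truth).astype(str)
    if pred.shape != truth.shape:
        raise ValidationError("pred/truth length mismatch")
    if pred.size == 0:
        raise ValidationError("empty label arrays")
    unknown = set(truth.tolist()) - set(classes)
    if unknown:
        raise ValidationError(f"truth labels outside class set: {sorted(unknown)}")
    out = {}
    for cls in classes:
        p = pred == cls
        t = truth == cls
        out[cls] = ConfusionCounts(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                                   tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))
    return out


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, F1 from one-vs-rest counts."""
    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.info("metrics: %s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    return {
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        "specificity": ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        "accuracy": ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        "f1": ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "f1"),
    }


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney pair probability (ties 1/2) for binary one-vs-rest truth."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if truth.shape != scores.shape:
        raise ValidationError("scores/truth length mismatch")
    if truth.all() or (~truth).all():
        logger.info("roc_auc undefined: single-class truth")
        return float("nan")
    return float(roc_auc_score(truth, scores))


def weighted_accuracy(counts: Mapping[str, ConfusionCounts],
                      supports: Mapping[str, int] | None = None,
                      mode: str = "support") -> float:
    """Support-weighted (default) or macro-averaged mean of per-class recall.

    With support weights this equals pooled accuracy over the test pixels;
    the macro mode weights classes equally (balanced accuracy).
    """
    if mode not in ("support", "macro"):
        raise ValidationError(f"unknown mode {mode!r}")
    recalls, weights = [], []
    for cls, c in counts.items():
        sup = c.support if supports is None else supports[cls]
        if sup < 0:
            raise ValidationError("supports must be >= 0")
        if sup == 0:
            continue
        recalls.append(c.tp / (c.tp + c.fn) if c.tp + c.fn else np.nan)
        weights.append(sup if mode == "support" else 1)
    if not weights:
        raise ValidationError("all class supports are zero")
    return float(np.average(recalls, weights=weights))


@dataclass
class FoldReport:
    """Per-patient (per-fold) metric bundle."""

    patient_id: str
    per_class: dict[str, dict[str, float]]
    weighted_accuracy: float
    macro_accuracy: float
    correct: bool
    n_pixels: int
    train_patients: tuple[str, ...] = ()


@dataclass
class CohortReport:
    """Arm-level aggregation: per-class mean +- SD of each metric over folds."""

    arm: str
    mean: pd.DataFrame          # metrics x classes
    sd: pd.DataFrame
    n_folds: int
    fraction_correct: float
    n_defined: pd.DataFrame     # folds contributing to each mean

    def to_dataframe(self, percent: bool = True) -> pd.DataFrame:
        """Human-readable table: 'mean +- SD' as percentages."""
        scale = 100.0 if percent else 1.0
        out = {}
        for cls in self.mean.columns:
            out[cls] = [f"{self.mean.loc[m, cls] * scale:.1f} ± "
                        f"{self.sd.loc[m, cls] * scale:.1f}"
                        for m in self.mean.index]
        return pd.DataFrame(out, index=self.mean.index)


def _aggregate(arm: str, folds: list[FoldReport]) -> CohortReport:
    mean = pd.DataFrame(index=list(METRIC_NAMES), columns=list(CLASSES_3), dtype=float)
    sd = pd.DataFrame(index=list(METRIC_NAMES), columns=list(CLASSES_3), dtype=float)
    n_def = pd.DataFrame(0, index=list(METRIC_NAMES), columns=list(CLASSES_3))
    for metric in METRIC_NAMES:
        for cls in CLASSES_3:
            vals = np.array([f.per_class[cls][metric] for f in folds], dtype=float)
            defined = vals[np.isfinite(vals)]
            n_def.loc[metric, cls] = defined.size
            if defined.size < len(folds):
                logger.info("%s: %s/%s undefined in %d folds", arm, cls, metric,
                            len(folds) - defined.size)
            mean.loc[metric, cls] = defined.mean() if defined.size else np.nan
            sd.loc[metric, cls] = defined.std(ddof=1) if defined.size > 1 else 0.0
    frac = float(np.mean([f.correct for f in folds])) if folds else float("nan")
    return CohortReport(arm, mean, sd, len(folds), frac, n_def)


def _fold_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).generate_state(2 * n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in children]


def select_arm(table: SpectrumTable, arm: str) -> SpectrumTable:
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}; choose from {ARMS}")
    if arm in ("all-hsi", "all-rgb"):
        return table
    treated = np.array([table.patients[str(p)].neoadjuvant != "none"
                        for p in table.patient_ids])
    return table.subset(treated if arm == "ctx" else ~treated)


def evaluate_fold(truth: np.ndarray, pred: np.ndarray,
                  scores: np.ndarray, classes: Sequence[str] = CLASSES_3
                  ) -> tuple[dict[str, dict[str, float]], float, float]:
    """Per-class metrics + weighted/macro accuracy for one test patient."""
    counts = confusion(pred, truth, classes)
    per_class = {}
    for j, cls in enumerate(classes):
        m = metrics(counts[cls])
        m["roc_auc"] = roc_auc(scores[:, j], np.asarray(truth).astype(str) == cls)
        per_class[cls] = m
    wa = weighted_accuracy(counts)
    macro = weighted_accuracy(counts, mode="macro")
    return per_class, wa, macro


def lopocv(table: SpectrumTable, arm: str = "all-hsi",
           pre_config: PreprocessConfig | None = None,
           mlp_config: MLPConfig | None = None,
           return_models: bool = False):
    """Leave-one-patient-out cross-validation of one evaluation arm.

    ``table`` carries 4-class labels and full-window spectra.  Features are
    extracted once (per-pixel, fold-independent); each fold balances the
    training rows on the 4-class labels, merges EAC+stroma, fits the MLP and
    scores the held-out patient's pixels.  Patients with no annotated pixels
    are skipped with a warning.  Returns ``(CohortReport, [FoldReport])``
    and, with ``return_models=True``, the per-fold models keyed by patient.
    """
    pre_config = pre_config or PreprocessConfig()
    arm_table = select_arm(table, arm)
    patients = sorted(set(arm_table.patient_ids.astype(str).tolist()))
    if len(patients) < 2:
        raise ValidationError(f"arm {arm!r} has {len(patients)} patients; need >= 2")
    variant = "rgb3" if arm == "all-rgb" else "hsi8"
    feature_cols = list(RGB_FEATURES if variant == "rgb3" else HSI_FEATURES)
    if mlp_config is None:
        mlp_config = MLPConfig(input_dim=len(feature_cols))

    df = extract_features(arm_table, pre_config, variant=variant)
    X = df[feature_cols].to_numpy()
    labels4 = df["label"].to_numpy()
    labels3 = np.array([merged_label(str(l)) for l in labels4], dtype=object)
    pids = df["patient_id"].to_numpy()

    seeds = _fold_seeds(mlp_config.rng_seed, len(patients))
    folds: list[FoldReport] = []
    models: dict[str, TrainedModel] = {}
    for k, held_out in enumerate(patients):
        test_mask = pids == held_out
        if not test_mask.any():
            warnings.warn(f"patient {held_out} has no annotated pixels; fold skipped")
            continue
        train_mask = ~test_mask
        train_idx = np.nonzero(train_mask)[0]
        assert not set(pids[train_idx]) & {held_out}, "fold leakage"
        bal = train_idx[balance(labels4[train_idx], rng_seed=seeds[2 * k])]
        fold_cfg = dataclasses.replace(mlp_config, rng_seed=seeds[2 * k + 1],
                                       input_dim=len(feature_cols))
        model = train_mlp(X[bal], labels3[bal], fold_cfg, variant=variant)
        scores = model.predict_scores(X[test_mask])
        pred = np.array([model.classes[i] for i in np.argmax(scores, axis=1)],
                        dtype=object)
        per_class, wa, macro = evaluate_fold(labels3[test_mask], pred, scores)
        folds.append(FoldReport(held_out, per_class, wa, macro,
                                wa > CORRECT_THRESHOLD, int(test_mask.sum()),
                                tuple(p for p in patients if p != held_out)))
        if return_models:
            models[held_out] = model
    report = _aggregate(arm, folds)
    if return_models:
        return report, folds, models
    return report, folds


def compare_auc(folds_a: Sequence[FoldReport], folds_b: Sequence[FoldReport],
                alpha: float = 0.05) -> pd.DataFrame:
    """Two-tailed paired t-test on per-patient ROC-AUC, per class.

    Pairs the two report sets by patient id (they must cover the same
    patients).  All-zero differences are a degenerate case: reported as
    t = 0, p = 1, flagged non-significant.
    """
    by_a = {f.patient_id: f for f in folds_a}
    by_b = {f.patient_id: f for f in folds_b}
    if set(by_a) != set(by_b):
        raise ValidationError("fold sets cover different patients")
    if len(by_a) < 3:
        raise ValidationError("paired t-test needs >= 3 patients")
    rows = []
    for cls in CLASSES_3:
        pairs = [(by_a[p].per_class[cls]["roc_auc"], by_b[p].per_class[cls]["roc_auc"])
                 for p in sorted(by_a)]
        pairs = [(a, b) for a, b in pairs if np.isfinite(a) and np.isfinite(b)]
        diffs = np.array([a - b for a, b in pairs])
        degenerate = False
        if diffs.size < 3:
            t, p = float("nan"), float("nan")
            degenerate = True
        elif np.allclose(diffs, 0.0):
            t, p, degenerate = 0.0, 1.0, True
            logger.info("compare_auc: degenerate zero differences for %s", cls)
        else:
            t, p = stats.ttest_rel([a for a, _ in pairs], [b for _, b in pairs])
            t, p = float(t), float(p)
        rows.append({"class": cls, "t": t, "p": p, "n": diffs.size,
                     "significant": bool(np.isfinite(p) and p < alpha),
                     "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("class")


def tnm_grading_cv(features: pd.DataFrame, target: str,
                   patients: Mapping[str, "object"],
                   specs: Sequence[AuxClassifierSpec] | None = None,
                   rng_seed: int = 0, n_splits: int = 10,
                   test_fraction: float = 0.3) -> pd.DataFrame:
    """Patient-category classification from tumor pixel features.

    ``features`` must hold the feature columns plus ``patient_id``; the
    target level (one of T/N/M/G) comes from the patient records.  Ten
    repeated patient-grouped 70/30 splits keep all pixels of a patient on
    one side of every split.  Levels with fewer than 2 patients are dropped
    with a warning; at least two levels must remain.  Returns per-classifier
    mean/SD pixel accuracy with the best classifier flagged (ties go to the
    simpler model).
    """
    if target not in ("T", "N", "M", "G"):
        raise ValidationError("target must be one of T, N, M, G")
    if specs is None:
        specs = [AuxClassifierSpec(kind, rng_seed=rng_seed)
                 for kind in AUX_SIMPLICITY_ORDER]
    pids = features["patient_id"].astype(str).to_numpy()
    level = np.array([getattr(patients[p], target) for p in pids], dtype=object)

    keep = np.ones(len(features), dtype=bool)
    for lv in sorted(set(level.tolist())):
        n_pat = len(set(pids[level == lv]))
        if n_pat < 2:
            warnings.warn(f"{target}={lv!r} has a single patient; level dropped")
            keep &= level != lv
    pids, level = pids[keep], level[keep]
    feature_cols = [c for c in features.columns if c not in ("patient_id", "label", "y", "x")]
    X = features.loc[keep, feature_cols].to_numpy()
    remaining = sorted(set(level.tolist()))
    if len(remaining) < 2:
        raise ValidationError(f"target {target} has < 2 usable levels")

    splitter = GroupShuffleSplit(n_splits=n_splits, test_size=test_fraction,
                                 random_state=rng_seed)
    accs: dict[str, list[float]] = {s.kind: [] for s in specs}
    for train_idx, test_idx in splitter.split(X, level, groups=pids):
        assert not set(pids[train_idx]) & set(pids[test_idx]), "group leakage"
        if len(set(level[train_idx].tolist())) < 2:
            continue
        for spec in specs:
            aux = train_aux(spec, X[train_idx], level[train_idx])
            pred = aux.predict(X[test_idx])
            accs[spec.kind].append(float((pred == level[test_idx].astype(str)).mean()))
    rows = []
    for spec in specs:
        vals = np.array(accs[spec.kind])
        rows.append({"classifier": spec.kind,
                     "mean_accuracy": float(vals.mean()) if vals.size else float("nan"),
                     "sd_accuracy": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     "n_splits": int(vals.size)})
    out = pd.DataFrame(rows).set_index("classifier")
    best_acc = out["mean_accuracy"].max()
    best = next(k for k in AUX_SIMPLICITY_ORDER
                if k in out.index and np.isclose(out.loc[k, "mean_accuracy"], best_acc))
    out["best"] = [k == best for k in out.index]
    return out
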