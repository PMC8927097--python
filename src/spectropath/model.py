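"""Class balancing, MLP training, pixel-wise prediction, auxiliary classifiers.

The main classifier is a small multi-layer perceptron: two hidden layers of
32 and 16 tanh units trained with the Adam stochastic optimizer on the
8-feature (or 3-channel RGB) pixel vectors.  Features are standardized to
zero mean / unit variance with training-fold statistics only -- tanh
saturates on unbounded ratio features otherwise -- and the scaler travels
with the model.  Class scores are the network's output layer normalized to a
simplex; prediction takes the argmax, ties resolved toward the first class
in the fixed order (tumor, squamous, background).

Balancing follows the annotation-imbalance rule: EAC, stroma and background
are each randomly downsampled (without replacement) to the squamous count,
squamous itself untouched.  It is applied on the 4-class table *before* the
EAC+stroma merge, and only inside each training fold -- test pixels keep
their natural distribution.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .annotation import CLASSES_3, SQUAMOUS, UNCLASSIFIED
from .cube_io import Hypercube
from .errors import ConfigurationError, TrainingError, ValidationError
from .features import HSI_FEATURES, RGB_FEATURES, extract_features
from .preprocess import PreprocessConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLPConfig:
    """Architecture is fixed (32/16 hidden tanh units, Adam); the rest is tunable.

    max_epochs / batch_size / learning_rate are ordinary Adam settings;
    training stops early once the training loss plateaus for
    ``n_iter_no_change`` epochs (tolerance ``tol``).  ``rng_seed`` is
    mandatory: weight initialization and minibatch shuffling are seeded.
    """

    hidden_sizes: tuple[int, int] = (32, 16)
    activation: str = "tanh"
    solver: str = "adam"
    max_epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 1e-3
    n_iter_no_change: int = 10
    tol: float = 1e-4
    rng_seed: int = 0
    input_dim: int = 8

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 2:
            raise ConfigurationError("exactly two hidden layers required")
        if self.activation != "tanh" or self.solver != "adam":
            raise ConfigurationError("activation is fixed to tanh, solver to adam")
        if self.input_dim < 1:
            raise ConfigurationError("input_dim must be >= 1 (8 for HSI, 3 for RGB)")


def balance(labels: np.ndarray, rng_seed: int,
            reference: str = SQUAMOUS) -> np.ndarray:
    """Row indices after downsampling every other class to the reference count.

    Operates on 4-class labels before merging.  Classes already at or below
    the reference count are kept whole (upsampling would duplicate pixels);
    a warning notes any such class.  Output indices are sorted, so the
    original row order is preserved.
    """
    labels = np.asarray(labels).astype(str)
    ref_count = int((labels == reference).sum())
    if ref_count == 0:
        raise ValidationError(f"reference class {reference!r} absent")
    rng = np.random.default_rng(rng_seed)
    keep: list[np.ndarray] = []
    for lab in dict.fromkeys(labels.tolist()):
        idx = np.nonzero(labels == lab)[0]
        if lab == reference or idx.size <= ref_count:
            if lab != reference and idx.size < ref_count:
                warnings.warn(f"class {lab!r} has {idx.size} < {ref_count} rows; kept whole")
            keep.append(idx)
        else:
            keep.append(rng.choice(idx, size=ref_count, replace=False))
    return np.sort(np.concatenate(keep))


@dataclass
class TrainedModel:
    """Fitted network plus the standardizer, class order and training manifest."""

    scaler: StandardScaler
    net: MLPClassifier
    classes: tuple[str, ...]
    variant: str
    manifest: dict[str, Any] = field(default_factory=dict)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) simplex scores in the fixed class order."""
        X = np.asarray(X, dtype=np.float64)
        proba = self.net.predict_proba(self.scaler.transform(X))
        out = np.zeros((X.shape[0], len(self.classes)))
        for j, cls in enumerate(self.net.classes_):
            out[:, self.classes.index(str(cls))] = proba[:, j]
        return out

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(X)
        # np.argmax keeps the first maximum: ties break toward the first
        # class in the fixed order
        return np.array([self.classes[i] for i in np.argmax(scores, axis=1)],
                        dtype=object)


def train_mlp(X: np.ndarray, y: np.ndarray, config: MLPConfig,
              variant: str = "hsi8") -> TrainedModel:
    """Fit the 32/16 tanh MLP on merged 3-class labels."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(str)
    if X.ndim != 2 or X.shape[1] != config.input_dim:
        raise ValidationError(f"feature dim {X.shape} != input_dim {config.input_dim}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    present = sorted(set(y.tolist()))
    if len(present) < 2:
        raise TrainingError("training needs at least 2 classes")

    scaler = StandardScaler().fit(X)
    net = MLPClassifier(hidden_layer_sizes=config.hidden_sizes,
                        activation=config.activation,
                        solver=config.solver,
                        learning_rate_init=config.learning_rate,
                        batch_size=min(config.batch_size, X.shape[0]),
                        max_iter=config.max_epochs,
                        n_iter_no_change=config.n_iter_no_change,
                        tol=config.tol,
                        random_state=config.rng_seed)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(scaler.transform(X), y)
    counts = {lab: int((y == lab).sum()) for lab in present}
    # keep the full fixed order when labels come from the merged taxonomy
    classes = CLASSES_3 if set(present) <= set(CLASSES_3) else tuple(present)
    manifest = {"config": {**asdict(config),
                           "hidden_sizes": list(config.hidden_sizes)},
                "variant": variant,
                "class_counts": counts, "n_iter": int(net.n_iter_),
                "final_loss": float(net.loss_)}
    logger.info("train_mlp: %d rows, classes %s, %d epochs, loss %.4g",
                X.shape[0], counts, net.n_iter_, net.loss_)
    return TrainedModel(scaler, net, classes, variant, manifest)


def predict_map(model: TrainedModel, cube: Hypercube,
                config: PreprocessConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise classification of a whole cube.

    Returns ``(label_image, score_image)``: an ``(h, w)`` object array of
    class labels (invalid-feature pixels marked ``unclassified``) and an
    ``(h, w, n_classes)`` score array in the model's class order.
    """
    feature_cols = list(HSI_FEATURES if model.variant == "hsi8" else RGB_FEATURES)
    expected = 8 if model.variant == "hsi8" else 3
    if model.net.n_features_in_ != expected:
        raise ConfigurationError("model/variant feature-count mismatch")
    df = extract_features(cube, config, variant=model.variant)
    h, w, _ = cube.shape
    labels = np.full((h, w), UNCLASSIFIED, dtype=object)
    scores = np.zeros((h, w, len(model.classes)))
    if len(df):
        X = df[feature_cols].to_numpy()
        sc = model.predict_scores(X)
        yy = df["y"].to_numpy()
        xx = df["x"].to_numpy()
        scores[yy, xx, :] = sc
        idx = np.argmax(sc, axis=1)
        labels[yy, xx] = np.array([model.classes[i] for i in idx], dtype=object)
    return labels, scores


# ---------------------------------------------------------------------------
# Auxiliary classifiers (TNM / grading comparison set)
# ---------------------------------------------------------------------------

AUX_KINDS = ("logistic-regression", "support-vector-machine-poly-kernel",
             "random-forest", "multi-layer-perceptron")

#: tie-break order from simplest to most complex model
AUX_SIMPLICITY_ORDER = AUX_KINDS


@dataclass(frozen=True)
class AuxClassifierSpec:
    kind: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in AUX_KINDS:
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}; "
                                     f"choose from {AUX_KINDS}")


@dataclass
class AuxModel:
    spec: AuxClassifierSpec
    scaler: StandardScaler
    estimator: Any

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self.scaler.transform(np.asarray(X, float)))

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(np.asarray(X, float))
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(Xs)
        return self.estimator.decision_function(Xs)


def train_aux(spec: AuxClassifierSpec, X: np.ndarray, y: np.ndarray) -> AuxModel:
    """Fit one of the four comparison classifiers (seed-deterministic)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(str)
    if len(set(y.tolist())) < 2:
        raise TrainingError("training needs at least 2 label levels")
    hp = dict(spec.hyperparameters)
    if spec.kind == "logistic-regression":
        est = LogisticRegression(max_iter=hp.pop("max_iter", 2000),
                                 random_state=spec.rng_seed, **hp)
    elif spec.kind == "support-vector-machine-poly-kernel":
        est = SVC(kernel="poly", degree=hp.pop("degree", 3),
                  random_state=spec.rng_seed, **hp)
    elif spec.kind == "random-forest":
        est = RandomForestClassifier(n_estimators=hp.pop("n_estimators", 100),
                                     random_state=spec.rng_seed, **hp)
    else:  # multi-layer-perceptron
        est = MLPClassifier(hidden_layer_sizes=hp.pop("hidden_layer_sizes", (32, 16)),
                            activation="tanh", solver="adam",
                            max_iter=hp.pop("max_iter", 200),
                            random_state=spec.rng_seed, **hp)
    scaler = StandardScaler().fit(X)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(scaler.transform(X), y)
    return AuxModel(spec, scaler, est)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str) -> None:
    """Persist the fitted model as a single joblib bundle (manifest included)."""
    import joblib

    joblib.dump({"scaler": model.scaler, "net": model.net,
                 "classes": model.classes, "variant": model.variant,
                 "manifest_json": json.dumps(model.manifest, sort_keys=True)}, path)


def load_model(path: str) -> TrainedModel:
    import joblib

    d = joblib.load(path)
    return TrainedModel(d["scaler"], d["net"], tuple(d["classes"]), d["variant"],
                        json.loads(d["manifest_json"]))
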