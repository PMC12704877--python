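"""The 8-classifier bank behind a uniform fit/predict contract.

Configurations: SVM with rbf / poly / sigmoid / linear kernels, KNN,
decision tree, random forest, and a small neural-network classifier.
Crossed with the two extractor kinds (AEF, CF) they form the 16 pipeline
variants.  Learners delegate to scikit-learn; hyperparameter defaults are
deliberately plain (SVM C=1.0 with the scale gamma heuristic, KNN k=5
Euclidean, Gini trees, 100-tree forest, one 64-unit hidden layer for the
NN) and overridable per spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureSet

__all__ = [
    "ClassifierSpec", "FittedModel", "PredictionSet",
    "registry", "model_id", "fit", "predict",
    "write_predictions_csv", "read_predictions_csv",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration; ``code`` is its stable short name
    (SVMR, SVMP, SVMS, SVML, KNN, DT, NN, RF)."""

    family: str                      # {"SVM", "KNN", "DT", "RF", "NN"}
    code: str
    kernel: str | None = None        # SVM only
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.family == "SVM") != (self.kernel is not None):
            raise ValueError("kernel must be present iff family is SVM")


def registry(seed: int = 0) -> list[ClassifierSpec]:
    """The 8 bank configurations in stable order."""
    return [
        ClassifierSpec("SVM", "SVMR", kernel="rbf", seed=seed),
        ClassifierSpec("SVM", "SVMP", kernel="poly", seed=seed),
        ClassifierSpec("SVM", "SVMS", kernel="sigmoid", seed=seed),
        ClassifierSpec("SVM", "SVML", kernel="linear", seed=seed),
        ClassifierSpec("KNN", "KNN", seed=seed),
        ClassifierSpec("DT", "DT", seed=seed),
        ClassifierSpec("NN", "NN", seed=seed),
        ClassifierSpec("RF", "RF", seed=seed),
    ]


def model_id(extractor_kind: str, spec: ClassifierSpec) -> str:
    """E.g. ('AEF', SVMR) -> 'AEFSVMR'; ('CF', KNN) -> 'CFKNN'."""
    return f"{extractor_kind}{spec.code}"


@dataclass
class FittedModel:
    spec: ClassifierSpec
    estimator: object
    classes: np.ndarray
    n_features: int
    model_id: str = ""


@dataclass
class PredictionSet:
    """Hard labels plus continuous scores (positive-class probability, or
    the signed decision value for SVMs) for one model on one test set."""

    model_id: str
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores must have equal length")
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparams)
    if spec.family == "SVM":
        return SVC(kernel=spec.kernel, C=hp.pop("C", 1.0),
                   degree=hp.pop("degree", 3), gamma=hp.pop("gamma", "scale"),
                   random_state=spec.seed, **hp)
    if spec.family == "KNN":
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5),
                                    metric=hp.pop("metric", "euclidean"),
                                    **hp)
    if spec.family == "DT":
        return DecisionTreeClassifier(criterion=hp.pop("criterion", "gini"),
                                      random_state=spec.seed, **hp)
    if spec.family == "RF":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            criterion=hp.pop("criterion", "gini"),
            random_state=spec.seed, **hp)
    if spec.family == "NN":
        return MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64,)),
            activation=hp.pop("activation", "relu"),
            solver="adam", learning_rate_init=hp.pop("learning_rate", 1e-3),
            max_iter=hp.pop("max_iter", 300), random_state=spec.seed, **hp)
    raise ValueError(f"unknown classifier family {spec.family!r}")


def fit(spec: ClassifierSpec, features: FeatureSet | np.ndarray,
        labels: np.ndarray, extractor_kind: str | None = None) -> FittedModel:
    x = features.matrix if isinstance(features, FeatureSet) else \
        np.asarray(features, dtype=float)
    kind = extractor_kind or (features.extractor_kind
                              if isinstance(features, FeatureSet) else "")
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != y.shape[0]:
        raise ValueError("feature rows must equal label count")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    est = _build_estimator(spec)
    est.fit(x, y)
    return FittedModel(spec=spec, estimator=est, classes=est.classes_,
                       n_features=x.shape[1],
                       model_id=model_id(kind, spec) if kind else spec.code)


def predict(model: FittedModel,
            features: FeatureSet | np.ndarray) -> PredictionSet:
    """Hard labels and continuous scores on a test feature set."""
    x = features.matrix if isinstance(features, FeatureSet) else \
        np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ValueError(f"expected (n, {model.n_features}) features, "
                         f"got shape {x.shape}")
    if x.shape[0] == 0:
        return PredictionSet(model.model_id, np.empty(0, int), np.empty(0))
    hard = model.estimator.predict(x)
    if model.spec.family == "SVM":
        scores = model.estimator.decision_function(x)
    else:
        proba = model.estimator.predict_proba(x)
        pos_col = int(np.argmax(model.classes == 1))
        scores = proba[:, pos_col]
    return PredictionSet(model.model_id, hard, scores)


def write_predictions_csv(prediction_sets: list[PredictionSet],
                          truth: np.ndarray, path) -> None:
    """Long-format CSV: model_id, row_index, true_label, predicted_label,
    score — the input dialect of the McNemar operations."""
    truth = np.asarray(truth, dtype=int)
    frames = []
    for ps in prediction_sets:
        if ps.labels.shape[0] != truth.shape[0]:
            raise ValueError(f"{ps.model_id}: prediction length mismatch")
        frames.append(pd.DataFrame({
            "model_id": ps.model_id,
            "row_index": np.arange(truth.shape[0]),
            "true_label": truth,
            "predicted_label": ps.labels,
            "score": ps.scores,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_predictions_csv(path) -> tuple[list[PredictionSet], np.ndarray]:
    """Inverse of :func:`write_predictions_csv`; checks that every model
    covers the same row set with consistent truth labels."""
    df = pd.read_csv(path)
    required = {"model_id", "row_index", "true_label", "predicted_label",
                "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"predictions CSV must have columns {sorted(required)}")
    truth = None
    sets = []
    for mid, grp in df.groupby("model_id", sort=False):
        grp = grp.sort_values("row_index")
        t = grp["true_label"].to_numpy(int)
        if truth is None:
            truth = t
            rows = grp["row_index"].to_numpy(int)
        elif (t.shape != truth.shape or not np.array_equal(t, truth)
              or not np.array_equal(grp["row_index"].to_numpy(int), rows)):
            raise ValueError(f"{mid}: row set or truth labels mismatch")
        sets.append(PredictionSet(str(mid),
                                  grp["predicted_label"].to_numpy(int),
                                  grp["score"].to_numpy(float)))
    if truth is None:
        raise ValueError("predictions CSV is empty")
    return sets, truth
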