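"""Facial-action classification from 64-dimensional epoch feature vectors.

Three classifier families are provided:

* A one-vs-rest Gaussian-kernel SVM. The dual problems are solved with
  libsvm (via scikit-learn), but the decision function is evaluated by this
  module's own kernel expansion ``f_m(x) = sum_i alpha_i^m y_i K(x, x_i) + b_m``
  over the stored support vectors, and :func:`kkt_audit` checks dual
  feasibility (0 <= alpha_i <= C, sum alpha_i y_i = 0) after training.
* A random forest whose prediction is an explicit majority vote over the
  trees, with even-vote ties broken deterministically toward the lowest
  class index.
* A backpropagation neural network (BPNN): a fully-connected feedforward
  net with tanh hidden layers and a softmax output, trained by full-batch
  gradient descent with momentum on the cross-entropy loss.

Two tasks are supported: ``five_class`` (the five actions at forceful
intensity) and ``ten_class`` (action x intensity). Recall and F1 are
macro-averaged, and every report tags the averaging scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

__all__ = [
    "ACTION_ABBREV",
    "SplitSpec",
    "ClassificationReport",
    "SvmModel",
    "ForestModel",
    "BpnnModel",
    "train_svm",
    "train_random_forest",
    "train_bpnn",
    "kkt_audit",
    "split",
    "evaluate",
    "task_labels",
    "run_benchmark",
    "majority_vote",
]

#: Figure-style short labels for the five actions.
ACTION_ABBREV = {
    "close_eyes": "CE",
    "purse_lips": "PL",
    "raise_eyebrows": "RE",
    "lift_mouth_corners": "LCM",
    "frown": "FR",
}
_INTENSITY_ABBREV = {"normal": "N", "forceful": "F"}


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition: 80/20 by default, stratified, seeded."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class _Standardizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        return cls(mean=X.mean(axis=0), scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


def _validate_features(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D samples x features array")
    if len(y) != X.shape[0]:
        raise ValueError("label count must match sample count")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    return X, y


# ---------------------------------------------------------------------------
# SVM


@dataclass
class _BinarySvm:
    """One one-vs-rest subproblem: dual coefficients on support vectors."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i, one per support vector
    sv_labels: np.ndarray  # y_i in {-1, +1}
    intercept: float


@dataclass
class SvmModel:
    """One-vs-rest Gaussian-kernel SVM with explicit dual representation."""

    classes: np.ndarray
    binaries: list[_BinarySvm]
    gamma: float
    C: float
    n_train: int
    scaler: _Standardizer = field(repr=False, default=None)

    def decision_function(self, X) -> np.ndarray:
        """Own kernel-expansion evaluation of every per-class decision value."""
        X = self.scaler.transform(np.asarray(X, dtype=float))
        scores = np.empty((X.shape[0], len(self.binaries)))
        for m, bin_svm in enumerate(self.binaries):
            d2 = (
                np.sum(X**2, axis=1)[:, None]
                - 2.0 * X @ bin_svm.support_vectors.T
                + np.sum(bin_svm.support_vectors**2, axis=1)[None, :]
            )
            kernel = np.exp(-self.gamma * np.clip(d2, 0.0, None))
            scores[:, m] = kernel @ bin_svm.dual_coef + bin_svm.intercept
        return scores

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self.decision_function(X), axis=1)]


def train_svm(
    features,
    labels,
    C: float = 1.0,
    kernel_width: float | None = None,
    seed: int = 0,
) -> SvmModel:
    """Fit one Gaussian-kernel binary SVM per class against the rest.

    Features are standardized internally (transform stored on the model).
    ``kernel_width`` is the RBF gamma; the default is
    ``1 / (n_features * var(features))`` computed after standardization.
    """
    X, y = _validate_features(features, labels)
    scaler = _Standardizer.fit(X)
    Xs = scaler.transform(X)
    var = Xs.var()
    gamma = kernel_width if kernel_width is not None else 1.0 / (
        X.shape[1] * (var if var > 0 else 1.0)
    )
    classes = np.unique(y)
    binaries = []
    for cls in classes:
        y_bin = np.where(y == cls, 1.0, -1.0)
        svc = SVC(C=C, kernel="rbf", gamma=gamma, random_state=seed)
        svc.fit(Xs, y_bin)
        sv = svc.support_vectors_
        dual = svc.dual_coef_.ravel()
        # libsvm orients the binary problem by class order; flip so that the
        # positive class (+1) has positive dual coefficients.
        if svc.classes_[1] != 1.0:
            dual = -dual
            intercept = -float(svc.intercept_[0])
        else:
            intercept = float(svc.intercept_[0])
        sv_labels = y_bin[svc.support_]
        binaries.append(
            _BinarySvm(
                support_vectors=sv,
                dual_coef=dual,
                sv_labels=sv_labels,
                intercept=intercept,
            )
        )
    return SvmModel(
        classes=classes,
        binaries=binaries,
        gamma=gamma,
        C=C,
        n_train=X.shape[0],
        scaler=scaler,
    )


def kkt_audit(model: SvmModel, tol: float = 1e-6) -> dict[str, float]:
    """Dual-feasibility check over all one-vs-rest subproblems.

    Returns the largest bound violation of ``0 <= alpha <= C`` and the largest
    ``|sum alpha_i y_i|``; both should be ~0 for a converged solver.
    """
    worst_bound = 0.0
    worst_balance = 0.0
    for bin_svm in model.binaries:
        alpha = bin_svm.dual_coef * bin_svm.sv_labels
        worst_bound = max(
            worst_bound,
            float(np.max(np.maximum(-alpha, alpha - model.C), initial=0.0)),
        )
        worst_balance = max(worst_balance, float(abs(bin_svm.dual_coef.sum())))
    return {
        "max_bound_violation": worst_bound,
        "max_balance_violation": worst_balance,
        "feasible": float(worst_bound <= tol and worst_balance <= tol),
    }


# ---------------------------------------------------------------------------
# Random forest


def majority_vote(per_tree_predictions: np.ndarray, n_classes: int) -> np.ndarray:
    """Majority vote over trees (rows: trees, cols: samples), returning class
    indices; even votes break toward the lowest class index."""
    votes = np.apply_along_axis(
        lambda col: np.bincount(col, minlength=n_classes), 0, per_tree_predictions
    )
    return np.argmax(votes, axis=0)


@dataclass
class ForestModel:
    """Random forest with explicit majority voting over the fitted trees."""

    forest: RandomForestClassifier
    classes: np.ndarray

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        per_tree = np.stack(
            [tree.predict(X).astype(int) for tree in self.forest.estimators_]
        )
        return self.classes[majority_vote(per_tree, len(self.classes))]


def train_random_forest(
    features, labels, n_trees: int = 200, seed: int = 0, **kwargs
) -> ForestModel:
    """Bagged decision trees; prediction is a straight majority vote."""
    X, y = _validate_features(features, labels)
    classes = np.unique(y)
    y_idx = np.searchsorted(classes, y)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, **kwargs)
    forest.fit(X, y_idx)
    return ForestModel(forest=forest, classes=classes)


# ---------------------------------------------------------------------------
# BPNN


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class BpnnModel:
    """Feedforward net (tanh hidden layers, softmax output) trained by
    backpropagation; predictions standardize inputs with the stored scaler."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: np.ndarray
    scaler: _Standardizer
    loss_history: np.ndarray

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        activations = [X]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = activations[-1] @ w + b
            if i < len(self.weights) - 1:
                activations.append(np.tanh(z))
            else:
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                activations.append(e / e.sum(axis=1, keepdims=True))
        return activations

    def predict_proba(self, X) -> np.ndarray:
        X = self.scaler.transform(np.asarray(X, dtype=float))
        return self._forward(X)[-1]

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]


def train_bpnn(
    features,
    labels,
    hidden_sizes: Sequence[int] = (32,),
    epochs: int = 200,
    learning_rate: float = 0.05,
    momentum: float = 0.9,
    seed: int = 0,
) -> BpnnModel:
    """Train the BPNN with full-batch gradient descent plus momentum.

    ``epochs=0`` returns the randomly initialized (Glorot-uniform) network,
    useful as an untrained baseline. A non-finite loss raises
    :class:`DivergenceError` rather than failing silently. The cross-entropy
    loss per epoch is recorded in ``loss_history`` (entry 0 is the loss
    before any update).
    """
    X, y = _validate_features(features, labels)
    scaler = _Standardizer.fit(X)
    Xs = scaler.transform(X)
    classes = np.unique(y)
    y_idx = np.searchsorted(classes, y)
    onehot = np.eye(len(classes))[y_idx]

    rng = np.random.default_rng(seed)
    sizes = [X.shape[1], *hidden_sizes, len(classes)]
    weights, biases, vel_w, vel_b = [], [], [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
        vel_w.append(np.zeros((fan_in, fan_out)))
        vel_b.append(np.zeros(fan_out))

    model = BpnnModel(
        weights=weights,
        biases=biases,
        classes=classes,
        scaler=scaler,
        loss_history=np.empty(0),
    )
    n = Xs.shape[0]
    losses = []
    for epoch in range(epochs + 1):
        activations = model._forward(Xs)
        probs = activations[-1]
        with np.errstate(divide="ignore"):
            loss = float(-np.mean(np.sum(onehot * np.log(probs), axis=1)))
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        losses.append(loss)
        if epoch == epochs:
            break
        delta = (probs - onehot) / n
        for layer in reversed(range(len(weights))):
            grad_w = activations[layer].T @ delta
            grad_b = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ weights[layer].T) * (1.0 - activations[layer] ** 2)
            vel_w[layer] = momentum * vel_w[layer] - learning_rate * grad_w
            vel_b[layer] = momentum * vel_b[layer] - learning_rate * grad_b
            weights[layer] += vel_w[layer]
            biases[layer] += vel_b[layer]
    model.loss_history = np.asarray(losses)
    return model


# ---------------------------------------------------------------------------
# Splitting, evaluation, benchmark


def split(features, labels, spec: SplitSpec = SplitSpec()):
    """Seeded random partition into train and test sets.

    Returns ``(X_train, X_test, y_train, y_test)``; stratified by default
    (raises for singleton classes, as a stratum cannot be split).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if spec.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("stratified split needs >= 2 samples per class")
    return train_test_split(
        X,
        y,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=y if spec.stratified else None,
    )


@dataclass
class ClassificationReport:
    """Accuracy, macro recall/F1 and the confusion matrix on a test set."""

    accuracy: float
    recall: float
    f1: float
    averaging: str
    confusion: pd.DataFrame  # rows: true class, columns: predicted class
    labels: list


def evaluate(model, X_test, y_test) -> ClassificationReport:
    """Score a fitted model: accuracy, macro recall, macro F1, confusion."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    y_pred = model.predict(np.asarray(X_test, dtype=float))
    model_classes = set(np.asarray(model.classes).tolist())
    unknown = set(y_test.tolist()) - model_classes
    if unknown:
        raise ValueError(f"test labels outside the model vocabulary: {sorted(unknown)}")
    labels = sorted(model_classes | set(y_test.tolist()))
    cm = confusion_matrix(y_test, y_pred, labels=labels)
    return ClassificationReport(
        accuracy=float(np.mean(y_pred == y_test)),
        recall=float(recall_score(y_test, y_pred, labels=labels, average="macro", zero_division=0)),
        f1=float(f1_score(y_test, y_pred, labels=labels, average="macro", zero_division=0)),
        averaging="macro",
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        labels=labels,
    )


def task_labels(feature_matrix: pd.DataFrame, task: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Select rows and build label strings for a classification task.

    ``five_class`` keeps forceful epochs only, labelled by action
    abbreviation (CE, PL, RE, LCM, FR); ``ten_class`` keeps everything,
    labelled ``<action>_<N|F>``.
    """
    if "action" not in feature_matrix or "intensity" not in feature_matrix:
        raise ValueError("feature matrix must carry 'action' and 'intensity' columns")
    if task == "five_class":
        df = feature_matrix[feature_matrix["intensity"] == "forceful"]
        if df.empty:
            raise ValueError("five_class task needs forceful-intensity epochs")
        labels = df["action"].map(ACTION_ABBREV).to_numpy()
    elif task == "ten_class":
        df = feature_matrix
        labels = (
            df["action"].map(ACTION_ABBREV)
            + "_"
            + df["intensity"].map(_INTENSITY_ABBREV)
        ).to_numpy()
    else:
        raise ValueError(f"unknown task {task!r}")
    feature_cols = [c for c in df.columns if c not in ("action", "intensity")]
    return df[feature_cols], labels


_TRAINERS = {
    "svm": train_svm,
    "rf": train_random_forest,
    "bpnn": train_bpnn,
}


def run_benchmark(
    feature_matrix: pd.DataFrame,
    task: str = "five_class",
    classifiers: Sequence[str] = ("svm", "rf", "bpnn"),
    spec: SplitSpec | None = None,
    seed: int = 0,
    classifier_params: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, ClassificationReport]]:
    """Train and evaluate the requested classifiers on one task.

    Returns a tidy results table (one row per classifier: accuracy, recall,
    F1, macro-averaged) and the full per-classifier reports with confusion
    matrices. A single seeded random split is used for all classifiers.
    """
    spec = spec or SplitSpec(seed=seed)
    params = classifier_params or {}
    X_df, y = task_labels(feature_matrix, task)
    X_train, X_test, y_train, y_test = split(X_df.to_numpy(), y, spec)
    rows = []
    reports: dict[str, ClassificationReport] = {}
    for name in classifiers:
        if name not in _TRAINERS:
            raise ValueError(f"unknown classifier {name!r}")
        model = _TRAINERS[name](X_train, y_train, seed=seed, **params.get(name, {}))
        report = evaluate(model, X_test, y_test)
        reports[name] = report
        rows.append(
            {
                "task": task,
                "classifier": name,
                "accuracy": report.accuracy,
                "recall": report.recall,
                "f1": report.f1,
                "averaging": report.averaging,
            }
        )
    return pd.DataFrame(rows), reports
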