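"""Classifier construction, training and hyper-parameter search.

Four model kinds share one predict contract (per-endpoint probabilities in
[0, 1], thresholded at 0.5 with ties counted positive): single-task and
multi-task feed-forward networks (authored in :mod:`hepatox._mlp`) and
Random Forest / SVM baselines built on scikit-learn.  Hyper-parameters are
tuned by exhaustive grid search or seeded randomized search with k-fold
cross validation and the F1 score as the objective.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid, ParameterSampler, \
    StratifiedKFold
from sklearn.svm import SVC

from ._mlp import MLP


@dataclass
class SingleTaskNetConfig:
    """Fully connected binary classifier: ReLU hidden layers, one sigmoid
    output unit, Adam + binary cross-entropy, dropout on input and hidden
    activations, early stopping on a stratified validation split."""

    n_hidden_layers: int = 2
    nodes_per_layer: tuple[int, ...] | int = 64
    dropout_rate: float = 0.3
    batch_size: int = 64
    max_epochs: int = 200
    early_stopping_patience: int = 10
    learning_rate: float = 1e-3
    seed: int = 0

    def layer_sizes(self) -> list[int]:
        if isinstance(self.nodes_per_layer, int):
            return [self.nodes_per_layer] * self.n_hidden_layers
        sizes = list(self.nodes_per_layer)
        if len(sizes) != self.n_hidden_layers:
            raise ValueError("nodes_per_layer length != n_hidden_layers")
        return sizes

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")


@dataclass
class MultiTaskNetConfig:
    """Hard-parameter-sharing network: shared ReLU trunk, one branch per
    endpoint (task-specific hidden layers + sigmoid head), loss = weighted
    sum of per-task binary cross-entropies."""

    n_shared_layers: int = 2
    n_task_layers: int = 1
    nodes_per_layer: int = 64
    task_loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dropout_rate: float = 0.3
    batch_size: int = 64
    max_epochs: int = 200
    early_stopping_patience: int = 10
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.task_loss_weights) != 3:
            raise ValueError("task_loss_weights must have length 3")
        if any(w < 0 for w in self.task_loss_weights) or \
                sum(self.task_loss_weights) == 0:
            raise ValueError("task_loss_weights must be non-negative and "
                             "not all zero")


@dataclass
class RFConfig:
    n_trees: int = 500
    min_impurity_decrease: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_impurity_decrease < 0:
            raise ValueError("invalid random-forest parameters")


@dataclass
class SVMConfig:
    kernel: str = "rbf"
    gamma: float | str = "scale"
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class BaselineConfig:
    rf: RFConfig = field(default_factory=RFConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)


@dataclass
class TrainedModel:
    """Uniform handle over a fitted classifier.

    ``model`` exposes ``predict_proba``; for the sklearn baselines it is
    wrapped so probabilities come out as an (n, 1) column like the nets.
    """

    kind: str                  # dnn_single | dnn_multi | rf | svm
    model: Any
    n_outputs: int
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, features) -> np.ndarray:
        return self.model.predict_proba(np.asarray(features, dtype=float))


def predict(model: TrainedModel, features, threshold: float = 0.5
            ) -> tuple[np.ndarray, np.ndarray]:
    """Binary calls and probabilities; probability == threshold counts as
    positive.  Shape (n, n_outputs)."""
    proba = model.predict_proba(features)
    return (proba >= threshold).astype(int), proba


def _check_binary(y: np.ndarray, what: str = "labels") -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError(f"{what} must be 0/1, got {classes}")
    if len(classes) < 2:
        raise ValueError(f"{what} contain a single class; cannot train")
    return y


class _SkProbaWrapper:
    """Adapts sklearn's (n, 2) predict_proba to the (n, 1) net contract."""

    def __init__(self, estimator):
        self.estimator = estimator
        self._pos_col = int(np.where(estimator.classes_ == 1)[0][0])

    def predict_proba(self, X):
        return self.estimator.predict_proba(X)[:, [self._pos_col]]


def build_and_train_single(features, labels,
                           config: SingleTaskNetConfig = SingleTaskNetConfig()
                           ) -> TrainedModel:
    X = np.asarray(features, dtype=float)
    y = _check_binary(labels)
    net = MLP(X.shape[1], config.layer_sizes(), task_layers=[], n_tasks=1,
              dropout_rate=config.dropout_rate, seed=config.seed)
    net.fit(X, y, batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            patience=config.early_stopping_patience,
            learning_rate=config.learning_rate)
    return TrainedModel(
        "dnn_single", net, 1,
        {"config": asdict(config), "epochs_run": net.n_epochs_run,
         "final_loss": net.history["best_val_loss"],
         "loss_history": net.history, "seed": config.seed})


def build_and_train_multi(features, label_matrix,
                          config: MultiTaskNetConfig = MultiTaskNetConfig()
                          ) -> TrainedModel:
    X = np.asarray(features, dtype=float)
    Y = np.asarray(label_matrix)
    if Y.ndim != 2 or Y.shape[1] != 3:
        raise ValueError("multi-task training expects an (n, 3) label matrix")
    for t in range(3):
        if config.task_loss_weights[t] > 0:
            _check_binary(Y[:, t], what=f"endpoint {t} labels")
    net = MLP(X.shape[1],
              [config.nodes_per_layer] * config.n_shared_layers,
              [config.nodes_per_layer] * config.n_task_layers,
              n_tasks=3, dropout_rate=config.dropout_rate,
              task_weights=config.task_loss_weights, seed=config.seed)
    net.fit(X, Y, batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            patience=config.early_stopping_patience,
            learning_rate=config.learning_rate)
    return TrainedModel(
        "dnn_multi", net, 3,
        {"config": asdict(config), "epochs_run": net.n_epochs_run,
         "final_loss": net.history["best_val_loss"],
         "loss_history": net.history, "seed": config.seed})


def build_and_train_rf(features, labels, config: RFConfig = RFConfig()
                       ) -> TrainedModel:
    X = np.asarray(features, dtype=float)
    y = _check_binary(labels)
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        min_impurity_decrease=config.min_impurity_decrease,
        random_state=config.seed, n_jobs=1).fit(X, y)
    return TrainedModel("rf", _SkProbaWrapper(est), 1,
                        {"config": asdict(config), "seed": config.seed})


def build_and_train_svm(features, labels, config: SVMConfig = SVMConfig()
                        ) -> TrainedModel:
    X = np.asarray(features, dtype=float)
    y = _check_binary(labels)
    est = SVC(kernel=config.kernel, gamma=config.gamma, C=config.C,
              probability=True, random_state=config.seed).fit(X, y)
    return TrainedModel("svm", _SkProbaWrapper(est), 1,
                        {"config": asdict(config), "seed": config.seed})


# ---------------------------------------------------------------------------
# hyper-parameter search

Builder = Callable[[np.ndarray, np.ndarray, dict], TrainedModel]


def _cv_f1(builder: Builder, params: dict, X, y, k_folds: int, seed: int,
           smote=None) -> float:
    from .evalkit import confusion, f1  # local import: avoid cycle
    from .rebalance import smote_oversample, SmoteConfig

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    scores = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[tr], y[tr]
        if smote is not None:
            cfg = SmoteConfig(k_neighbors=smote.k_neighbors,
                              target_ratio=smote.target_ratio,
                              seed=smote.seed + fold)
            X_tr, y_tr = smote_oversample(X_tr, y_tr, cfg)
        model = builder(X_tr, y_tr, params)
        pred, _ = predict(model, X[te])
        scores.append(f1(confusion(y[te], pred[:, 0])))
    return float(np.mean(scores))


def grid_search(builder: Builder, space: dict, features, labels,
                k_folds: int = 3, seed: int = 0, smote=None
                ) -> tuple[dict, list[tuple[dict, float]]]:
    """Exhaustive search over a discrete grid, mean cross-validated F1 as
    the objective; ties broken by earliest grid enumeration order."""
    X = np.asarray(features, dtype=float)
    y = _check_binary(labels)
    if not space:
        raise ValueError("empty hyper-parameter grid")
    candidates = list(ParameterGrid(space))
    if not candidates:
        raise ValueError("empty hyper-parameter grid")
    results, best, best_score = [], None, -np.inf
    errors = []
    for params in candidates:
        try:
            score = _cv_f1(builder, params, X, y, k_folds, seed, smote)
        except (ValueError, FloatingPointError) as exc:
            errors.append((params, exc))
            continue
        results.append((params, score))
        if score > best_score:  # strict > keeps the earliest tie winner
            best, best_score = params, score
    if best is None:
        raise RuntimeError(
            f"all {len(candidates)} grid candidates failed to train; "
            f"first error: {errors[0][1]}")
    return best, results


def randomized_search(builder: Builder, space: dict, n_draws: int,
                      features, labels, k_folds: int = 3, seed: int = 0,
                      smote=None) -> tuple[dict, list[tuple[dict, float]]]:
    """Randomized search: ``n_draws`` seeded draws from ``space`` (lists or
    scipy distributions), same objective and tie rule as grid_search."""
    X = np.asarray(features, dtype=float)
    y = _check_binary(labels)
    candidates = list(ParameterSampler(space, n_iter=n_draws,
                                       random_state=seed))
    results, best, best_score = [], None, -np.inf
    errors = []
    for params in candidates:
        try:
            score = _cv_f1(builder, params, X, y, k_folds, seed, smote)
        except (ValueError, FloatingPointError) as exc:
            errors.append((params, exc))
            continue
        results.append((params, score))
        if score > best_score:
            best, best_score = params, score
    if best is None:
        raise RuntimeError(
            f"all {len(candidates)} sampled candidates failed to train; "
            f"first error: {errors[0][1]}")
    return best, results


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Checkpoint layout: config.json (kind + metadata sans history) plus
    weights.npz for nets or estimator.pkl for baselines."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {k: v for k, v in model.metadata.items() if k != "loss_history"}
    (directory / "config.json").write_text(json.dumps(
        {"kind": model.kind, "n_outputs": model.n_outputs,
         "metadata": meta}, default=str))
    if model.kind.startswith("dnn"):
        net: MLP = model.model
        np.savez(directory / "weights.npz",
                 *net.get_weights(),
                 arch=np.array(json.dumps({
                     "n_features": net.n_features,
                     "shared_layers": net.shared_layers,
                     "task_layers": net.task_layers,
                     "n_tasks": net.n_tasks,
                     "dropout_rate": net.dropout_rate,
                     "task_weights": net.task_weights.tolist(),
                     "seed": net.seed})))
    else:
        with open(directory / "estimator.pkl", "wb") as fh:
            pickle.dump(model.model, fh)


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    spec = json.loads((directory / "config.json").read_text())
    if spec["kind"].startswith("dnn"):
        data = np.load(directory / "weights.npz", allow_pickle=False)
        arch = json.loads(str(data["arch"]))
        net = MLP(arch["n_features"], arch["shared_layers"],
                  arch["task_layers"], n_tasks=arch["n_tasks"],
                  dropout_rate=arch["dropout_rate"],
                  task_weights=arch["task_weights"], seed=arch["seed"])
        weights = [data[f"arr_{i}"] for i in range(len(net.get_weights()))]
        net.set_weights(weights)
        obj = net
    else:
        with open(directory / "estimator.pkl", "rb") as fh:
            obj = pickle.load(fh)
    return TrainedModel(spec["kind"], obj, spec["n_outputs"],
                        spec.get("metadata", {}))
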