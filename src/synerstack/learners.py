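"""Base-learner zoo: six tabular families plus feed-forward networks.

Tabular families (random forest, extremely randomized trees, SVM, linear
SGD, k-NN, gradient-boosted trees) are fitted through scikit-learn/xgboost;
feed-forward networks use the in-package MLP (ReLU hidden layers, sigmoid or
linear head, Adam at learning rate 1e-4 for 125 epochs by default).
Hyperparameters are selected by grid search with 3-fold cross-validation on
a seeded 5% subsample of the training rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import (ExtraTreesClassifier, ExtraTreesRegressor,
                              RandomForestClassifier, RandomForestRegressor)
from sklearn.linear_model import SGDClassifier, SGDRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

from .nn import FeedForwardNet

__all__ = ["ModelConfig", "TrainedModel", "FAMILIES", "DEFAULT_ARCHITECTURES",
           "DEFAULT_GRIDS", "enumerate_grid", "grid_search", "train_model",
           "train_tabular", "train_net", "predict"]

FAMILIES = ("random_forest", "extremely_randomized_trees",
            "support_vector_machine", "linear_sgd", "k_nearest_neighbors",
            "gradient_boosted_trees", "feedforward_net")

# Twelve default net architectures (hidden widths); the grid is configurable.
DEFAULT_ARCHITECTURES = (
    [10, 10, 10], [100, 100, 100], [25, 25, 25], [50, 50, 50],
    [50], [100], [200], [100, 50], [200, 100], [50, 25],
    [200, 100, 50], [300, 150, 75],
)

DEFAULT_DROPOUTS = (0.0, 0.25, 0.5, 0.75)

# Standard per-family search axes; stand-ins for an externally defined grid.
DEFAULT_GRIDS = {
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "extremely_randomized_trees": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "support_vector_machine": {"C": [0.1, 1.0, 10.0], "kernel": ["rbf", "linear"]},
    "linear_sgd": {"alpha": [1e-4, 1e-3, 1e-2]},
    "k_nearest_neighbors": {"n_neighbors": [3, 5, 11], "weights": ["uniform", "distance"]},
    "gradient_boosted_trees": {"max_depth": [3, 6], "n_estimators": [100, 300],
                               "alpha": [0.0, 0.25]},
    "feedforward_net": {"architecture": list(DEFAULT_ARCHITECTURES),
                        "dropout": list(DEFAULT_DROPOUTS)},
}


@dataclass(frozen=True)
class ModelConfig:
    family: str
    task: str  # "classification" | "regression"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family: {self.family!r}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task: {self.task!r}")


@dataclass
class TrainedModel:
    config: ModelConfig
    estimator: object
    seed: int
    n_features: int
    loss_curve: list | None = None

    def predict(self, X):
        return predict(self, X)


def enumerate_grid(axes: dict) -> list[dict]:
    """Cartesian product of named axes, in deterministic insertion order."""
    if not axes:
        raise ValueError("no axes supplied")
    names = list(axes)
    for n in names:
        vals = list(axes[n])
        if not vals:
            raise ValueError(f"empty grid axis: {n!r}")
    return [dict(zip(names, combo))
            for combo in itertools.product(*(list(axes[n]) for n in names))]


def _make_tabular(config: ModelConfig, seed: int):
    hp = dict(config.hyperparameters)
    clf = config.task == "classification"
    fam = config.family
    if fam == "random_forest":
        cls = RandomForestClassifier if clf else RandomForestRegressor
        return cls(random_state=seed, **hp)
    if fam == "extremely_randomized_trees":
        cls = ExtraTreesClassifier if clf else ExtraTreesRegressor
        return cls(random_state=seed, **hp)
    if fam == "support_vector_machine":
        return SVC(random_state=seed, **hp) if clf else SVR(**hp)
    if fam == "linear_sgd":
        if clf:
            return SGDClassifier(random_state=seed, **hp)
        return SGDRegressor(random_state=seed, **hp)
    if fam == "k_nearest_neighbors":
        cls = KNeighborsClassifier if clf else KNeighborsRegressor
        return cls(**hp)
    if fam == "gradient_boosted_trees":
        if "alpha" in hp:  # L1 regularization weight
            hp["reg_alpha"] = hp.pop("alpha")
        cls = XGBClassifier if clf else XGBRegressor
        return cls(random_state=seed, verbosity=0, **hp)
    raise ValueError(f"not a tabular family: {fam!r}")


def train_tabular(config: ModelConfig, X, y, seed: int = 0) -> TrainedModel:
    """Fit one of the six tabular families with its hyperparameters."""
    X = np.asarray(X, dtype=float)
    est = _make_tabular(config, seed)
    est.fit(X, np.asarray(y))
    return TrainedModel(config, est, seed, X.shape[1])


def train_net(config: ModelConfig, X, y, seed: int = 0) -> TrainedModel:
    """Fit a feed-forward net: ReLU hidden layers, dropout after each one,
    sigmoid + binary cross-entropy head for classification or linear + MSE
    for regression."""
    X = np.asarray(X, dtype=float)
    hp = dict(config.hyperparameters)
    clf = config.task == "classification"
    net = FeedForwardNet(
        [X.shape[1]] + list(hp.get("architecture", [100, 100, 100])) + [1],
        out_activation="sigmoid" if clf else "linear",
        loss="bce" if clf else "mse",
        dropout=hp.get("dropout", 0.0),
        learning_rate=hp.get("learning_rate", 1e-4),
        epochs=hp.get("epochs", 125),
        batch_size=hp.get("batch_size", 32),
        seed=seed,
    )
    net.fit(X, np.asarray(y, dtype=float))
    return TrainedModel(config, net, seed, X.shape[1], loss_curve=net.loss_curve_)


def train_model(config: ModelConfig, X, y, seed: int = 0) -> TrainedModel:
    if config.family == "feedforward_net":
        return train_net(config, X, y, seed)
    return train_tabular(config, X, y, seed)


def predict(model: TrainedModel, X) -> np.ndarray:
    """Probability-like score (classification) or point prediction (regression).

    Margin-based families (SVM, linear SGD) map their decision score through
    a logistic link so every classifier emits a [0, 1] score.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.ndim} != "
            f"training width {model.n_features}")
    est = model.estimator
    if model.config.task == "classification":
        if isinstance(est, FeedForwardNet):
            return est.predict(X)
        if isinstance(est, (SVC, SGDClassifier)):
            return expit(est.decision_function(X))
        return est.predict_proba(X)[:, 1]
    return np.asarray(est.predict(X), dtype=float)


def grid_search(candidates, family: str, task: str, X, y, *, seed: int = 0,
                metric=None, maximize: bool = True, subsample_fraction: float = 0.05,
                folds: int = 3):
    """Select hyperparameters by k-fold CV on a seeded training subsample.

    ``candidates`` is a list of hyperparameter dicts (see
    :func:`enumerate_grid`); evaluation uses 3-fold CV on a 5% subsample of
    the training rows by default.  Ties break toward the earlier candidate,
    so the result is deterministic under a fixed seed.

    Returns (best ModelConfig, results DataFrame).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if metric is None:
        if task == "classification":
            metric, maximize = (lambda t, p: float(np.mean((p >= 0.5) == t))), True
        else:
            metric, maximize = (lambda t, p: float(np.sqrt(np.mean((p - t) ** 2)))), False
    rng = np.random.default_rng(seed)
    n_sub = max(int(round(subsample_fraction * len(y))), 0)
    if n_sub < 2 * folds:
        raise ValueError(
            f"subsample of {n_sub} rows is too small for {folds}-fold CV; "
            "increase subsample_fraction")
    idx = rng.choice(len(y), size=n_sub, replace=False)
    Xs, ys = X[idx], y[idx]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)

    records = []
    for rank, hp in enumerate(candidates):
        config = ModelConfig(family, task, hp)
        scores = []
        for tr, va in kf.split(Xs):
            model = train_model(config, Xs[tr], ys[tr], seed=seed)
            scores.append(metric(ys[va], predict(model, Xs[va])))
        records.append({"candidate": rank, "mean_score": float(np.mean(scores)),
                        **{f"param_{k}": str(v) for k, v in hp.items()}})
    results = pd.DataFrame(records)
    col = results["mean_score"].to_numpy()
    best_rank = int(np.argmax(col) if maximize else np.argmin(col))
    return ModelConfig(family, task, dict(candidates[best_rank])), results
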