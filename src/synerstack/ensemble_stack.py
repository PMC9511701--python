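"""Prediction-space stacking with outlier replacement.

Base-model predictions for each sample form a meta-feature row.  Before the
stacker sees them, runaway predictions are tamed: a value whose magnitude
exceeds 10x the magnitude of the mean of the *other* models' predictions for
that sample is replaced by that mean (the rule is skipped when the mean is
exactly zero, where it is undefined).  A shallow feed-forward network is then
trained on the cleaned meta-features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learners import TrainedModel, predict
from .nn import FeedForwardNet

__all__ = ["MetaFeatureTable", "EnsembleModel", "build_meta_features",
           "train_stacker", "predict_ensemble", "vote_tally"]

OUTLIER_FACTOR = 10.0


@dataclass
class MetaFeatureTable:
    values: pd.DataFrame                  # samples x base models
    replacements: list = field(default_factory=list)  # (row, col, old, new)


@dataclass
class EnsembleModel:
    stacker: FeedForwardNet
    base_models: list[TrainedModel]
    task: str
    model_ids: list[str]


def build_meta_features(predictions: dict) -> MetaFeatureTable:
    """Assemble and outlier-clean the per-model prediction table.

    ``predictions`` maps model id -> aligned prediction vector.  Replacing a
    value can expose a further outlier against the shrunken remaining mean,
    so the pass repeats until no value is flagged; the returned table is a
    fixed point of the rule (re-applying it changes nothing).  Termination
    is guaranteed: every replacement shrinks that cell's magnitude by more
    than 10x, so each cell can only be replaced finitely often before it
    underflows to zero, where the zero-mean guard stops the rule.
    """
    if len(predictions) < 2:
        raise ValueError("need at least 2 base models to stack")
    lengths = {len(v) for v in predictions.values()}
    if len(lengths) != 1:
        raise ValueError("base model prediction vectors are misaligned")
    df = pd.DataFrame(predictions)
    out = df.to_numpy(dtype=float)
    n_models = out.shape[1]
    log = []
    # realistic tables settle in 1-2 passes; the bound covers the worst case
    # of cells cascading all the way to floating-point underflow
    for _ in range(4000):
        total = out.sum(axis=1, keepdims=True)
        loo_mean = (total - out) / (n_models - 1)  # mean of the other models
        mask = (np.abs(out) > OUTLIER_FACTOR * np.abs(loo_mean)) & (loo_mean != 0)
        if not mask.any():
            break
        rows, cols = np.nonzero(mask)
        for r, c in zip(rows.tolist(), cols.tolist()):
            log.append((int(r), df.columns[c], float(out[r, c]),
                        float(loo_mean[r, c])))
        out[mask] = loo_mean[mask]
    return MetaFeatureTable(pd.DataFrame(out, columns=df.columns, index=df.index),
                            replacements=log)


def train_stacker(meta: MetaFeatureTable, targets, task: str, *,
                  hidden=(100, 100, 100), dropout: float = 0.6,
                  learning_rate: float = 1e-4, epochs: int = 3,
                  batch_size: int = 32, seed: int = 0) -> FeedForwardNet:
    """Train the shallow stacking network on cleaned meta-features.

    Defaults follow the reference recipe (Adam at 1e-4, 3 epochs, BCE/MSE
    loss by task; hidden widths and dropout grid-searchable).  At small
    sample sizes callers should raise ``epochs``/``learning_rate`` to keep
    the total weight-update count meaningful.
    """
    X = meta.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite meta features; run build_meta_features first")
    clf = task == "classification"
    net = FeedForwardNet(
        [X.shape[1]] + list(hidden) + [1],
        out_activation="sigmoid" if clf else "linear",
        loss="bce" if clf else "mse",
        dropout=dropout,
        learning_rate=learning_rate,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
    )
    net.fit(X, np.asarray(targets, dtype=float))
    return net


def predict_ensemble(model: EnsembleModel, X, *, return_base: bool = False):
    """Ensemble score per sample: base predictions -> outlier rule -> stacker."""
    preds = {mid: predict(m, X)
             for mid, m in zip(model.model_ids, model.base_models)}
    meta = build_meta_features(preds)
    scores = model.stacker.predict(meta.values.to_numpy(dtype=float))
    if return_base:
        return scores, meta.values
    return scores


def vote_tally(base_scores: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Count of base models calling each sample synergistic."""
    return (base_scores > threshold).sum(axis=1)
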