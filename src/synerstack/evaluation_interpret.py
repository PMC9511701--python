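"""Metric suites, permutation importance and PCA-propagated contributions.

Classification models are scored with accuracy, precision, recall, AUROC and
F1 at a configurable probability threshold; regressors with RMSE, MSE, MAE,
Pearson and Spearman.  Feature contribution is a two-stage analysis: seeded
permutation importance of the model's input columns on held-out rows, then
propagation of reduced-column importance back to original omics features
through squared PCA loadings, finally aggregated into per-block shares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)

__all__ = ["classification_metrics", "regression_metrics",
           "permutation_importance", "propagate_pca_importance", "block_share"]


def classification_metrics(truth, scores, threshold: float = 0.5) -> dict:
    """Confusion-matrix metrics at the threshold plus rank-based AUROC."""
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValueError("truth and scores must be the same length")
    hard = (scores >= threshold).astype(int)
    out = {
        "accuracy": float(accuracy_score(truth, hard)),
        "precision": float(precision_score(truth, hard, zero_division=0)),
        "recall": float(recall_score(truth, hard, zero_division=0)),
        "f1": float(f1_score(truth, hard, zero_division=0)),
        "n": int(len(truth)),
    }
    if len(np.unique(truth)) < 2:
        out["auroc"] = float("nan")  # undefined with a single class
    else:
        out["auroc"] = float(roc_auc_score(truth, scores))
    return out


def regression_metrics(truth, pred) -> dict:
    """RMSE/MSE/MAE plus Pearson and Spearman (mid-rank ties)."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must be the same length")
    err = pred - truth
    out = {
        "mse": float(np.mean(err**2)),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "n": int(len(truth)),
    }
    if len(truth) >= 3 and np.std(truth) > 0 and np.std(pred) > 0:
        out["pearson"] = float(pearsonr(truth, pred).statistic)
        out["spearman"] = float(spearmanr(truth, pred).statistic)
    else:
        out["pearson"] = out["spearman"] = float("nan")
    return out


def permutation_importance(predict_fn, X, y, metric, *, repeats: int = 10,
                           seed: int = 0, maximize: bool = True) -> np.ndarray:
    """Mean metric degradation when each input column is shuffled.

    ``predict_fn`` maps a feature matrix to scores; ``metric(truth, scores)``
    is the evaluation. Importance of column j is ``baseline - permuted``
    (negated for error metrics where lower is better), averaged over
    ``repeats`` seeded shuffles.  Intended for held-out rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    baseline = metric(y, predict_fn(X))
    sign = 1.0 if maximize else -1.0
    importances = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            drops.append(sign * (baseline - metric(y, predict_fn(Xp))))
        importances[j] = float(np.mean(drops))
    return importances


def propagate_pca_importance(component_importance, loadings: pd.DataFrame
                             ) -> pd.Series:
    """Spread reduced-column importance onto original features.

    weight(f) = sum_c importance(c) * loading(f, c)^2; with orthonormal
    loadings the squared loadings of each component sum to 1, so total
    importance mass is conserved.
    """
    imp = np.asarray(component_importance, dtype=float)
    if len(imp) != loadings.shape[1]:
        raise ValueError("one importance per component required")
    weights = (loadings.to_numpy() ** 2) @ imp
    return pd.Series(weights, index=loadings.index, name="weight")


def block_share(feature_weights: pd.Series, block_of: dict) -> pd.Series:
    """Percent share of total absolute importance per feature block."""
    unmapped = [f for f in feature_weights.index if f not in block_of]
    if unmapped:
        raise KeyError(f"features without a block mapping: {unmapped[:5]}")
    abs_w = feature_weights.abs()
    totals = abs_w.groupby(feature_weights.index.map(block_of)).sum()
    grand = totals.sum()
    if grand == 0:
        return totals * 0.0
    return 100.0 * totals / grand
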