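"""Binary synergy labels and the full-agreement classification dataset.

Each of the four reference-model scores is binarized at threshold 0 (strictly
above = synergistic).  A sample enters the classification dataset only when
all four per-model labels agree; disagreeing samples are dropped.  The CSS
sensitivity score is a regression target only and never votes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["SYNERGISTIC", "NONSYNERGISTIC", "DROPPED", "binarize",
           "full_agreement", "label_table", "AGREEMENT_MODELS"]

SYNERGISTIC = "synergistic"
NONSYNERGISTIC = "nonsynergistic"
DROPPED = "dropped"

AGREEMENT_MODELS = ("bliss", "hsa", "loewe", "zip")


def binarize(score: float, threshold: float = 0.0) -> str:
    """Score strictly above the threshold -> synergistic, else nonsynergistic."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return SYNERGISTIC if score > threshold else NONSYNERGISTIC


def full_agreement(labels) -> str:
    """Unanimous vote over the four reference-model labels, else dropped."""
    labels = list(labels)
    if len(labels) != 4:
        raise ValueError("full agreement requires exactly 4 labels (Bliss, HSA, Loewe, ZIP)")
    for lab in labels:
        if lab not in (SYNERGISTIC, NONSYNERGISTIC):
            raise ValueError(f"invalid label: {lab!r}")
    if all(lab == SYNERGISTIC for lab in labels):
        return SYNERGISTIC
    if all(lab == NONSYNERGISTIC for lab in labels):
        return NONSYNERGISTIC
    return DROPPED


def label_table(scores: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Per-model labels plus the agreement column for a scored table.

    Expects ``score_bliss``, ``score_hsa``, ``score_loewe``, ``score_zip``
    columns; key columns are carried through unchanged.
    """
    out = scores.copy()
    for model in AGREEMENT_MODELS:
        col = f"score_{model}"
        if col not in scores.columns:
            raise ValueError(f"missing score column: {col}")
        out[f"label_{model}"] = [binarize(s, threshold) for s in scores[col]]
    out["agreement_label"] = [
        full_agreement(row)
        for row in out[[f"label_{m}" for m in AGREEMENT_MODELS]].itertuples(index=False)
    ]
    return out
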