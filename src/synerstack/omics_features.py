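"""Per-block omics reduction: missing-value policies, PCA, hourglass autoencoders.

Seven omics blocks (expression, copy-number, methylation, chromatin
profiling, metabolomics, microRNA, proteomics) each hold a cells x features
matrix.  Every block is standardized, missing values handled by one of two
policies, then reduced either to 25 principal components or to the
bottleneck activations of a 7-layer hourglass autoencoder; the reduced
blocks concatenate into one profile per cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .nn import FeedForwardNet

__all__ = [
    "BLOCK_ORDER",
    "ReducedBlock",
    "handle_missing",
    "standardize_block",
    "pca_reduce",
    "autoencoder_bottleneck_width",
    "autoencoder_layer_widths",
    "build_autoencoder",
    "autoencoder_reduce",
    "assemble_cell_profile",
]

BLOCK_ORDER = ("expression", "cnv", "methylation", "chromatin",
               "metabolomics", "microrna", "proteomics")


@dataclass
class ReducedBlock:
    """Reduced representation of one omics block.

    ``scores`` is cells x reduced-features; for PCA the ``loadings``
    (features x components) and per-component ``explained_variance`` ratios
    are kept for importance propagation, for autoencoders the trained
    ``encoder`` is kept instead.
    """

    name: str
    method: str
    scores: pd.DataFrame
    loadings: pd.DataFrame | None = None
    explained_variance: np.ndarray | None = None
    encoder: FeedForwardNet | None = field(default=None, repr=False)


def handle_missing(block: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Apply a missing-value policy: drop whole cell rows, or fill zeros.

    ``fill_zero`` is meant to run on standardized data, where 0 is the
    column mean, making it mean-imputation in the original units.
    """
    if policy == "drop_sample":
        out = block.dropna(axis=0, how="any")
        if out.empty:
            raise ValueError("all rows dropped by drop_sample policy")
        return out
    if policy == "fill_zero":
        return block.fillna(0.0)
    raise ValueError(f"unknown missing-value policy: {policy!r}")


def standardize_block(block: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (population variance) ignoring missing entries.

    Zero-variance columns map to 0 rather than erroring; omics blocks
    legitimately contain near-constant features.
    """
    values = block.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=0)
    std = np.nanstd(values, axis=0, ddof=0)
    std = np.where(std == 0.0, 1.0, std)
    return pd.DataFrame((values - mean) / std, index=block.index,
                        columns=block.columns)


def pca_reduce(block: pd.DataFrame, n_components: int = 25, *,
               name: str = "block") -> ReducedBlock:
    """PCA scores/loadings/explained variance with a fixed sign convention.

    Each component is flipped so its largest-magnitude loading is positive,
    making outputs reproducible across platforms.
    """
    if block.isna().any().any():
        raise ValueError("missing values present; run handle_missing first")
    if len(block) < n_components:
        raise ValueError(
            f"{len(block)} rows < {n_components} requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(block.to_numpy(dtype=float))
    loadings = pca.components_.T  # features x components
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    scores, loadings = scores * flip, loadings * flip
    cols = [f"{name}_pc{i + 1}" for i in range(n_components)]
    return ReducedBlock(
        name=name,
        method="pca",
        scores=pd.DataFrame(scores, index=block.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=block.columns, columns=cols),
        explained_variance=pca.explained_variance_ratio_.copy(),
    )


def autoencoder_bottleneck_width(n_features: int) -> int:
    """Bottleneck sizing rule: divisor 50 / 10 / 2 by input width."""
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if n_features >= 10_000:
        return n_features // 50
    if n_features >= 500:
        return n_features // 10
    return n_features // 2


def autoencoder_layer_widths(n_features: int) -> list[int]:
    """Symmetric 7-layer hourglass: input, 5 hidden (incl. bottleneck), output.

    The two encoder hidden widths interpolate geometrically between the
    input and bottleneck widths (mirrored in the decoder).
    """
    b = autoencoder_bottleneck_width(n_features)
    h1 = int(round(n_features ** (2 / 3) * b ** (1 / 3)))
    h2 = int(round(n_features ** (1 / 3) * b ** (2 / 3)))
    # keep a strict hourglass whenever the widths leave room for one
    h1 = min(max(h1, b + 2), max(n_features - 1, b + 2))
    h2 = min(max(h2, b + 1), max(h1 - 1, b + 1))
    return [n_features, h1, h2, b, h2, h1, n_features]


def _epochs_for(n_features: int) -> int:
    if n_features <= 500:
        return 1000
    if n_features <= 10_000:
        return 250
    return 100


def build_autoencoder(n_features: int, *, seed: int = 0, epochs: int | None = None,
                      learning_rate: float = 1e-3) -> FeedForwardNet:
    """7-layer hourglass autoencoder (5 hidden layers), ReLU throughout.

    Adam optimizer at learning rate 1e-3 with MSE reconstruction loss;
    the epoch count follows the block-size rule (1000 / 250 / 100 epochs
    for <=500 / <=10,000 / larger feature counts) unless overridden.
    """
    widths = autoencoder_layer_widths(n_features)
    return FeedForwardNet(
        widths,
        out_activation="relu",
        loss="mse",
        learning_rate=learning_rate,
        epochs=_epochs_for(n_features) if epochs is None else epochs,
        batch_size=32,
        seed=seed,
    )


_BOTTLENECK_LAYER = 2  # hidden index of the bottleneck in the 7-layer stack


def autoencoder_reduce(block: pd.DataFrame, *, seed: int = 0,
                       epochs: int | None = None, name: str = "block") -> ReducedBlock:
    """Train the hourglass autoencoder and return bottleneck activations."""
    if block.isna().any().any():
        raise ValueError("missing values present; run handle_missing first")
    net = build_autoencoder(block.shape[1], seed=seed, epochs=epochs)
    X = block.to_numpy(dtype=float)
    net.fit(X, X)
    z = net.hidden_activations(X, _BOTTLENECK_LAYER)
    cols = [f"{name}_ae{i + 1}" for i in range(z.shape[1])]
    return ReducedBlock(name=name, method="autoencoder",
                        scores=pd.DataFrame(z, index=block.index, columns=cols),
                        encoder=net)


def assemble_cell_profile(reduced_blocks: dict, annotations: pd.DataFrame
                          ) -> pd.DataFrame:
    """Inner-join the seven reduced blocks into one profile per cell line.

    Blocks concatenate in the fixed order of :data:`BLOCK_ORDER`; the tissue
    annotation attaches as a ``tissue`` column (empty annotations become
    ``"unknown"`` and are flagged rather than dropped).
    """
    missing = set(BLOCK_ORDER) - set(reduced_blocks)
    if missing:
        raise ValueError(f"missing blocks: {sorted(missing)}")
    parts = []
    for name in BLOCK_ORDER:
        blk = reduced_blocks[name]
        parts.append(blk.scores if isinstance(blk, ReducedBlock) else blk)
    profile = pd.concat(parts, axis=1, join="inner")
    tissue = annotations.set_index("cell")["tissue"] if "cell" in annotations.columns \
        else annotations["tissue"]
    profile["tissue"] = tissue.reindex(profile.index).fillna("unknown")
    return profile
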