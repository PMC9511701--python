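"""Model-ready tables: feature joins, drug clustering and hold-out splits.

A sample is one (drug1, drug2, cell) triple; its feature vector concatenates
the two drugs' standardized descriptors with the cell-line profile.  Four
evaluation sets are carved out: an 80/20 train/test split plus three
leave-group-out scenarios (whole cell lines, whole drugs, whole drug pairs)
with no key leakage into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

__all__ = ["AssembledDataset", "SplitPlan", "join_features", "cluster_drugs",
           "make_holdouts", "SPLIT_TAGS"]

KEYS = ["drug1", "drug2", "cell"]
SPLIT_TAGS = ("train", "test", "leave_cells_out", "leave_drugs_out",
              "leave_combos_out")


@dataclass
class AssembledDataset:
    """Joined feature/target table keyed by (drug1, drug2, cell)."""

    table: pd.DataFrame
    feature_cols: list[str]
    target_cols: list[str]
    exclusions: dict = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return self.table[self.feature_cols].to_numpy(dtype=float)

    def rows(self, tag: str) -> pd.DataFrame:
        return self.table[self.table["split"] == tag]


@dataclass(frozen=True)
class SplitPlan:
    held_cells: tuple
    held_drugs: tuple
    held_pairs: tuple
    seed: int
    test_fraction: float


def join_features(scores: pd.DataFrame, labels: pd.DataFrame,
                  descriptors: pd.DataFrame, profiles: pd.DataFrame
                  ) -> AssembledDataset:
    """Inner-join synergy targets with drug descriptors and cell profiles.

    Rows whose drug lacks descriptors or whose cell lacks a profile are
    excluded and counted in ``exclusions``; duplicate (pair, cell) keys are
    an error.
    """
    if scores.duplicated(subset=KEYS).any():
        raise ValueError("duplicate (drug1, drug2, cell) keys in scores")
    merged = scores.merge(labels[KEYS + ["agreement_label"]], on=KEYS, how="left")

    prof = profiles.drop(columns=["tissue"], errors="ignore")
    exclusions = {
        "missing_drug1_descriptors": int((~merged["drug1"].isin(descriptors.index)).sum()),
        "missing_drug2_descriptors": int((~merged["drug2"].isin(descriptors.index)).sum()),
        "missing_cell_profile": int((~merged["cell"].isin(prof.index)).sum()),
    }
    keep = (merged["drug1"].isin(descriptors.index)
            & merged["drug2"].isin(descriptors.index)
            & merged["cell"].isin(prof.index))
    merged = merged[keep].reset_index(drop=True)
    if merged.empty:
        raise ValueError(f"empty join; per-source exclusions: {exclusions}")

    d1 = descriptors.loc[merged["drug1"]].to_numpy(dtype=float)
    d2 = descriptors.loc[merged["drug2"]].to_numpy(dtype=float)
    cp = prof.loc[merged["cell"]].to_numpy(dtype=float)
    feat_cols = ([f"d1_{c}" for c in descriptors.columns]
                 + [f"d2_{c}" for c in descriptors.columns]
                 + [f"cell_{c}" for c in prof.columns])
    features = pd.DataFrame(np.hstack([d1, d2, cp]), columns=feat_cols)
    target_cols = [c for c in merged.columns if c.startswith("score_")]
    table = pd.concat([merged.reset_index(drop=True), features], axis=1)
    if "tissue" in profiles.columns:
        table["tissue"] = profiles["tissue"].reindex(table["cell"]).to_numpy()
    return AssembledDataset(table=table, feature_cols=feat_cols,
                            target_cols=target_cols, exclusions=exclusions)


def cluster_drugs(descriptors: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Hierarchical (average-linkage, Euclidean) clustering of drugs."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if len(descriptors) < n_clusters:
        raise ValueError("fewer drugs than requested clusters")
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="average",
                                    metric="euclidean")
    labels = model.fit_predict(descriptors.to_numpy(dtype=float))
    return pd.Series(labels, index=descriptors.index, name="cluster")


def _canonical_pair(a, b):
    return (a, b) if a <= b else (b, a)


def make_holdouts(dataset: AssembledDataset, annotations: pd.DataFrame,
                  clusters: pd.Series, seed: int, *, n_cells: int = 3,
                  n_drugs: int = 5, n_pairs: int = 5,
                  test_fraction: float = 0.2) -> SplitPlan:
    """Tag every row with one of the five split labels, leakage-free.

    Hold-out precedence is cells, then drugs, then pairs: rows touching an
    earlier hold-out never re-enter a later pool.  Held-out cells must span
    distinct tissues and held-out drugs come from distinct descriptor
    clusters where available.  The remaining pool splits 80/20 at the row
    level with the given seed; the tags are written into ``dataset.table``.
    """
    rng = np.random.default_rng(seed)
    table = dataset.table
    tissue_of = annotations.set_index("cell")["tissue"]

    cells = sorted(table["cell"].unique())
    tissues = sorted({tissue_of.get(c, "unknown") for c in cells})
    if len(tissues) < n_cells:
        raise ValueError(
            f"need >= {n_cells} tissues for the cell hold-out, found {len(tissues)}")
    chosen_tissues = list(rng.choice(tissues, size=n_cells, replace=False))
    held_cells = []
    for t in chosen_tissues:
        members = sorted(c for c in cells if tissue_of.get(c, "unknown") == t)
        held_cells.append(members[rng.integers(len(members))])

    pool = table[~table["cell"].isin(held_cells)]
    drugs = sorted(set(pool["drug1"]) | set(pool["drug2"]))
    drug_clusters = clusters.reindex(drugs)
    cluster_ids = sorted(drug_clusters.dropna().unique())
    rng.shuffle(cluster_ids)
    held_drugs: list = []
    for cid in cluster_ids:  # one drug per cluster first, then wrap around
        if len(held_drugs) == n_drugs:
            break
        members = sorted(d for d in drugs
                         if drug_clusters.get(d) == cid and d not in held_drugs)
        if members:
            held_drugs.append(members[rng.integers(len(members))])
    while len(held_drugs) < n_drugs:
        rest = [d for d in drugs if d not in held_drugs]
        if not rest:
            raise ValueError("not enough drugs for the drug hold-out")
        held_drugs.append(rest[rng.integers(len(rest))])

    pool = pool[~(pool["drug1"].isin(held_drugs) | pool["drug2"].isin(held_drugs))]
    pairs = sorted({_canonical_pair(a, b)
                    for a, b in zip(pool["drug1"], pool["drug2"])})
    if len(pairs) < n_pairs:
        raise ValueError(
            f"need >= {n_pairs} spare drug pairs, found {len(pairs)}")
    held_pairs = [pairs[i] for i in rng.choice(len(pairs), size=n_pairs,
                                               replace=False)]

    tags = pd.Series("train", index=table.index)
    in_cells = table["cell"].isin(held_cells)
    in_drugs = (table["drug1"].isin(held_drugs)
                | table["drug2"].isin(held_drugs)) & ~in_cells
    pair_key = [_canonical_pair(a, b) for a, b in zip(table["drug1"], table["drug2"])]
    in_pairs = pd.Series(pair_key, index=table.index).isin(held_pairs) \
        & ~in_cells & ~in_drugs
    tags[in_cells] = "leave_cells_out"
    tags[in_drugs] = "leave_drugs_out"
    tags[in_pairs] = "leave_combos_out"

    remaining = tags.index[tags == "train"].to_numpy()
    n_test = int(round(test_fraction * len(remaining)))
    test_idx = rng.choice(remaining, size=n_test, replace=False)
    tags[test_idx] = "test"
    dataset.table["split"] = tags
    return SplitPlan(tuple(held_cells), tuple(held_drugs),
                     tuple(map(tuple, held_pairs)), seed, test_fraction)
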