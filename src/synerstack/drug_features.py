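"""Per-drug molecular descriptor tables: computation, filtering, scaling.

Descriptor tables have one row per drug id and one named column per numeric
descriptor.  Preprocessing drops any column that is non-numeric, contains
missing values, or has zero variance across drugs, then z-scores the
survivors (population variance, i.e. the standard-scaler convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DESCRIPTOR_CATEGORIES",
    "FilterReport",
    "StandardizeStats",
    "compute_descriptors",
    "filter_descriptors",
    "standardize",
]

# Descriptor-category bookkeeping for a filtered 2-D descriptor set:
# (category, class E=energetic / P=pharmacological / S=structural /
# M=miscellaneous, retained feature count).  The 28 categories total 586
# retained descriptors.
DESCRIPTOR_CATEGORIES = (
    ("Acidity/Basicity", "E", 2),
    ("ADME", "P", 3),
    ("Aromatics", "S", 2),
    ("Atom Count", "S", 16),
    ("Atom-Bond Connectivity", "S", 2),
    ("Autocorrelation", "M", 180),
    ("Bond Count", "S", 9),
    ("Atomic Orbitals", "E", 10),
    ("Chirality", "S", 38),
    ("Constitutional", "S", 14),
    ("Energy State", "E", 68),
    ("Fragment Complexity", "S", 1),
    ("Framework", "S", 1),
    ("Hydrogen Bonds", "S", 2),
    ("Information Content", "S", 36),
    ("Molecular Complexity", "S", 1),
    ("Molecular Operating Environment", "P", 51),
    ("Molecule Graph", "S", 5),
    ("Path Count", "S", 21),
    ("Polarizability", "E", 2),
    ("Ring Count", "S", 66),
    ("Rotatable Bonds", "S", 1),
    ("Topological Charges", "S", 21),
    ("Topological Index", "S", 7),
    ("Topological Polar Surface Area", "S", 2),
    ("Walk Counts", "S", 21),
    ("Weight", "S", 2),
    ("Wildman-Crippen", "M", 2),
)


@dataclass
class FilterReport:
    kept: list
    dropped_non_numeric: list
    dropped_zero_variance: list

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_non_numeric) + len(self.dropped_zero_variance)


@dataclass
class StandardizeStats:
    """Fitted per-column means and scales, reusable in transform mode."""

    mean: pd.Series
    scale: pd.Series


def compute_descriptors(smiles: dict) -> tuple[pd.DataFrame, dict]:
    """2-D molecular descriptors from SMILES, one row per drug id.

    Requires RDKit.  Returns (table, errors) where ``errors`` maps drug ids
    whose SMILES failed to parse to a message; failures never abort the
    whole batch.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    rows, errors = {}, {}
    for drug_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            errors[drug_id] = f"unparseable SMILES: {smi!r}"
            continue
        rows[drug_id] = Descriptors.CalcMolDescriptors(mol)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "drug"
    return table, errors


def _numeric_or_none(col: pd.Series):
    try:
        out = pd.to_numeric(col, errors="raise")
    except (ValueError, TypeError):
        return None
    if out.isna().any() or not np.all(np.isfinite(out.to_numpy(dtype=float))):
        return None
    return out.astype(float)


def filter_descriptors(table: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop non-numeric (incl. any-missing) and zero-variance columns."""
    if table.empty:
        raise ValueError("empty descriptor table")
    if len(table) < 2:
        raise ValueError("need at least 2 drugs to assess descriptor variance")
    kept, non_num, zero_var = {}, [], []
    for name in table.columns:
        col = _numeric_or_none(table[name])
        if col is None:
            non_num.append(name)
        elif np.ptp(col.to_numpy()) == 0.0:
            zero_var.append(name)
        else:
            kept[name] = col
    report = FilterReport(list(kept), non_num, zero_var)
    return pd.DataFrame(kept, index=table.index), report


def standardize(table: pd.DataFrame, stats: StandardizeStats | None = None
                ) -> tuple[pd.DataFrame, StandardizeStats]:
    """Z-score each column (population variance); reuse ``stats`` if given.

    Fitting on the training drugs and passing the returned stats for any
    held-out drugs keeps the scaling leak-free.
    """
    values = table.to_numpy(dtype=float)
    if stats is None:
        mean = table.mean(axis=0)
        scale = pd.Series(values.std(axis=0, ddof=0), index=table.columns)
        if (scale == 0).any():
            bad = list(scale.index[scale == 0])
            raise ValueError(f"zero-variance columns (run filter first): {bad}")
        stats = StandardizeStats(mean=mean, scale=scale)
    else:
        missing = set(table.columns) - set(stats.mean.index)
        if missing:
            raise ValueError(f"columns without fitted stats: {sorted(missing)}")
    out = (table - stats.mean[table.columns]) / stats.scale[table.columns]
    return out, stats
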