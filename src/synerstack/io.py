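"""Readers/writers for the delimited-text study formats.

Long-format combination tables carry one row per (drug1, drug2, cell,
conc1, conc2, response); monotherapy tables one row per (drug, cell, conc,
response).  Responses may arrive as growth percentages (screen convention)
or inhibition fractions; everything is converted to inhibition fractions at
ingestion and drug pairs are put in canonical (lexicographic) order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .reference_models import DoseResponseMatrix

__all__ = ["read_combination_table", "read_monotherapy_table",
           "matrices_from_tables", "read_descriptor_table", "read_smiles_file",
           "read_omics_blocks", "read_annotations", "to_inhibition"]

COMBO_COLUMNS = ["drug1", "drug2", "cell", "conc1", "conc2", "response"]
MONO_COLUMNS = ["drug", "cell", "conc", "response"]


def to_inhibition(values, unit: str):
    """Convert responses to the canonical inhibition-fraction scale.

    ``growth_pct`` uses inhibition = (100 - growth) / 100; out-of-range
    results (cytotoxic or over-growth wells) are passed through untouched.
    """
    values = np.asarray(values, dtype=float)
    if unit == "inhibition_frac":
        return values
    if unit == "growth_pct":
        return (100.0 - values) / 100.0
    raise ValueError(f"unknown response unit: {unit!r}")


def read_combination_table(path, response_unit: str = "inhibition_frac") -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COMBO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"combination table missing columns: {missing}")
    unit = df["response_unit"].iloc[0] if "response_unit" in df.columns else response_unit
    df["response"] = to_inhibition(df["response"], unit)
    swap = df["drug1"] > df["drug2"]
    df.loc[swap, ["drug1", "drug2"]] = df.loc[swap, ["drug2", "drug1"]].to_numpy()
    df.loc[swap, ["conc1", "conc2"]] = df.loc[swap, ["conc2", "conc1"]].to_numpy()
    return df[COMBO_COLUMNS]


def read_monotherapy_table(path, response_unit: str = "inhibition_frac") -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MONO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"monotherapy table missing columns: {missing}")
    unit = df["response_unit"].iloc[0] if "response_unit" in df.columns else response_unit
    df["response"] = to_inhibition(df["response"], unit)
    return df[MONO_COLUMNS]


def matrices_from_tables(combos: pd.DataFrame, mono: pd.DataFrame) -> list:
    """Build one DoseResponseMatrix per (drug1, drug2, cell) group."""
    mono_idx = {k: g for k, g in mono.groupby(["drug", "cell"])}

    def series(drug, cell):
        try:
            g = mono_idx[(drug, cell)]
        except KeyError:
            raise ValueError(f"no monotherapy series for drug {drug} on cell {cell}")
        return g["conc"].to_numpy(float), g["response"].to_numpy(float)

    out = []
    for (d1, d2, cell), g in combos.groupby(["drug1", "drug2", "cell"]):
        out.append(DoseResponseMatrix(
            d1, d2, cell,
            g["conc1"].to_numpy(float), g["conc2"].to_numpy(float),
            g["response"].to_numpy(float),
            series(d1, cell), series(d2, cell)))
    return out


def read_descriptor_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "drug"
    return df


def read_smiles_file(path) -> dict:
    """One ``id<TAB>SMILES`` per line."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        drug_id, smi = line.split("\t", 1)
        out[drug_id] = smi.strip()
    return out


def read_omics_blocks(block_dir) -> dict:
    """All ``<block>.csv`` files in a directory, keyed by block name."""
    blocks = {}
    for path in sorted(Path(block_dir).glob("*.csv")):
        df = pd.read_csv(path, index_col=0)
        df.index.name = "cell"
        blocks[path.stem] = df
    if not blocks:
        raise ValueError(f"no block CSVs found in {block_dir}")
    return blocks


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"cell", "tissue"} <= set(df.columns):
        raise ValueError("annotation table needs 'cell' and 'tissue' columns")
    return df[["cell", "tissue"]]
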