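"""Self-contained synthetic drug-combination studies with known ground truth.

The generator emulates the structure of a public combination screen joined
to a multi-omics cell-line panel: Hill-shaped monotherapy curves, 3x3 or
5x3 combination dose grids whose responses follow the Bliss expectation
plus an injected synergy offset delta and Gaussian noise, drug descriptor
tables built from cluster archetypes (with deliberately unusable columns to
exercise filtering), and seven low-rank omics blocks with missing values.
The injected delta is modulated by a cell latent factor that also drives
one omics block, so cell features carry real predictive signal.  Every draw
comes from one seeded generator, making bundles byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hill import HillCurve, hill_response
from .reference_models import DoseResponseMatrix, expected_bliss

__all__ = ["SyntheticConfig", "StudyBundle", "simulate_drugs", "simulate_cells",
           "simulate_combinations", "simulate_study", "DEFAULT_BLOCK_SPECS"]

# (feature count, latent rank) per omics block at desk scale
DEFAULT_BLOCK_SPECS = {
    "expression": (120, 4),
    "cnv": (60, 3),
    "methylation": (80, 3),
    "chromatin": (40, 3),
    "metabolomics": (50, 3),
    "microrna": (60, 3),
    "proteomics": (40, 3),
}


@dataclass
class SyntheticConfig:
    """Study-shape and signal parameters for the generator.

    The defaults describe the desk-scale study used throughout the test
    suite: 20 drugs over 5 descriptor archetypes, 12 cell lines over 4
    tissues, 50 drug pairs per cell line (600 matrices), 3x3 positive dose
    grids, and a synergy-offset mixture with a point mass at zero.
    """

    n_drugs: int = 20
    n_cells: int = 12
    n_tissues: int = 4
    n_pairs: int = 50
    grid_shape: tuple = (3, 3)
    # drug descriptors
    n_descriptors: int = 30
    n_archetypes: int = 5
    descriptor_noise: float = 0.3
    n_junk_constant: int = 2
    n_junk_text: int = 1
    # monotherapy Hill priors
    emax_range: tuple = (0.6, 1.0)
    m_log10_range: tuple = (-1.0, 1.0)
    lam_range: tuple = (0.8, 2.5)
    # synergy offset mixture: P(zero), P(positive), remainder negative
    weight_zero: float = 0.3
    weight_pos: float = 0.45
    delta_magnitude: tuple = (0.03, 0.15)
    delta_mode: str = "pair_cell"  # or "cell_only"
    noise_sigma: float = 0.02
    # omics
    block_specs: dict = field(default_factory=lambda: dict(DEFAULT_BLOCK_SPECS))
    block_noise: float = 0.3
    missing_rate: float = 0.02
    signal_block: str = "expression"
    seed: int = 0

    def __post_init__(self):
        if self.n_tissues < 3:
            raise ValueError("need >= 3 tissues for the cell hold-out")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.weight_zero + self.weight_pos <= 1:
            raise ValueError("mixture weights must sum to <= 1")


@dataclass
class StudyBundle:
    config: SyntheticConfig
    descriptors: pd.DataFrame
    hill_truth: dict
    archetype_of: dict
    blocks: dict
    annotations: pd.DataFrame
    cell_factor: pd.Series
    matrices: list
    truth: pd.DataFrame


def _drug_ids(n):
    return [f"D{i:03d}" for i in range(1, n + 1)]


def _cell_ids(n):
    return [f"C{i:03d}" for i in range(1, n + 1)]


def simulate_drugs(config: SyntheticConfig, rng: np.random.Generator):
    """Drug table: ground-truth Hill curves + archetype-structured descriptors.

    Injects ``n_junk_constant`` zero-variance and ``n_junk_text`` non-numeric
    columns so descriptor filtering has real work to do.
    """
    ids = _drug_ids(config.n_drugs)
    archetypes = rng.normal(0.0, 1.0, size=(config.n_archetypes, config.n_descriptors))
    arch_of = {d: int(i % config.n_archetypes) for i, d in enumerate(ids)}
    rows = [archetypes[arch_of[d]]
            + rng.normal(0.0, config.descriptor_noise, config.n_descriptors)
            for d in ids]
    table = pd.DataFrame(rows, index=pd.Index(ids, name="drug"),
                         columns=[f"desc_{j:03d}" for j in range(config.n_descriptors)])
    for k in range(config.n_junk_constant):
        table[f"junk_const_{k}"] = 1.0
    for k in range(config.n_junk_text):
        table[f"junk_text_{k}"] = "not-a-number"

    curves = {}
    for d in ids:
        emax = rng.uniform(*config.emax_range)
        m = 10.0 ** rng.uniform(*config.m_log10_range)
        lam = rng.uniform(*config.lam_range)
        curves[d] = HillCurve(0.0, float(emax), float(m), float(lam))
    return table, curves, arch_of


def simulate_cells(config: SyntheticConfig, rng: np.random.Generator):
    """Seven low-rank omics blocks, tissue annotations and the signal factor.

    Each block is latent-factors x loadings + noise; the first latent factor
    of ``config.signal_block`` doubles as the cell's synergy-modulation
    factor, so that block genuinely drives the injected signal.
    """
    cells = _cell_ids(config.n_cells)
    blocks, factors = {}, {}
    for name, (n_feat, rank) in config.block_specs.items():
        Z = rng.normal(0.0, 1.0, size=(config.n_cells, rank))
        L = rng.normal(0.0, 1.0, size=(rank, n_feat))
        X = Z @ L + rng.normal(0.0, config.block_noise, size=(config.n_cells, n_feat))
        df = pd.DataFrame(X, index=pd.Index(cells, name="cell"),
                          columns=[f"{name}_f{j:04d}" for j in range(n_feat)])
        if config.missing_rate > 0:
            mask = rng.random(df.shape) < config.missing_rate
            df = df.mask(mask)
        blocks[name] = df
        factors[name] = Z
    if config.signal_block not in blocks:
        raise ValueError(f"signal block {config.signal_block!r} not generated")
    cell_factor = pd.Series(factors[config.signal_block][:, 0], index=cells,
                            name="signal_factor")
    tissues = [f"T{i % config.n_tissues + 1}" for i in range(config.n_cells)]
    annotations = pd.DataFrame({"cell": cells, "tissue": tissues})
    return blocks, annotations, cell_factor


def _draw_base_delta(config, rng, n):
    u = rng.random(n)
    mag = rng.uniform(*config.delta_magnitude, size=n)
    delta = np.where(u < config.weight_zero, 0.0,
                     np.where(u < config.weight_zero + config.weight_pos, mag, -mag))
    return delta


def _dose_ladder(curve: HillCurve, n: int = 5):
    return curve.m * np.logspace(-1.0, 1.0, n)


def simulate_combinations(config: SyntheticConfig, drug_curves: dict,
                          cell_factor: pd.Series, rng: np.random.Generator):
    """Dose-response matrices with Bliss-expectation responses + delta + noise.

    Monotherapy series (5 log-spaced doses around each drug's true midpoint)
    are drawn once per (drug, cell) and shared across that drug's matrices.
    Ground-truth delta per (pair, cell) is returned alongside.
    """
    ids = sorted(drug_curves)
    all_pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    if config.n_pairs > len(all_pairs):
        raise ValueError("n_pairs exceeds the number of distinct drug pairs")
    pick = rng.choice(len(all_pairs), size=config.n_pairs, replace=False)
    pairs = [all_pairs[i] for i in sorted(pick)]

    base_delta = {p: d for p, d in zip(pairs, _draw_base_delta(config, rng, len(pairs)))}
    cells = list(cell_factor.index)

    n1, n2 = config.grid_shape
    mono: dict = {}

    def mono_series(drug, cell):
        if (drug, cell) not in mono:
            doses = _dose_ladder(drug_curves[drug])
            resp = hill_response(doses, drug_curves[drug]) \
                + rng.normal(0.0, config.noise_sigma, len(doses))
            mono[(drug, cell)] = (doses, resp)
        return mono[(drug, cell)]

    def grid_doses(doses, k):
        # central k doses of the 5-point ladder (all 5 when k = 5)
        start = (len(doses) - k) // 2
        return doses[start:start + k]

    matrices, truth_rows = [], []
    for (a, b) in pairs:
        for cell in cells:
            s = float(cell_factor[cell])
            if config.delta_mode == "cell_only":
                delta = float(np.mean(config.delta_magnitude) * np.tanh(s))
            else:
                delta = float(base_delta[(a, b)] * (1.0 + 0.5 * np.tanh(s)))
            d1_mono = mono_series(a, cell)
            d2_mono = mono_series(b, cell)
            g1 = grid_doses(d1_mono[0], n1)
            g2 = grid_doses(d2_mono[0], n2)
            D1, D2 = np.meshgrid(g1, g2, indexing="ij")
            d1f, d2f = D1.ravel(), D2.ravel()
            y1 = hill_response(d1f, drug_curves[a])
            y2 = hill_response(d2f, drug_curves[b])
            y = expected_bliss(y1, y2) + delta \
                + rng.normal(0.0, config.noise_sigma, d1f.shape)
            matrices.append(DoseResponseMatrix(a, b, cell, d1f, d2f, y,
                                               d1_mono, d2_mono))
            truth_rows.append({"drug1": a, "drug2": b, "cell": cell,
                               "delta": delta})
    return matrices, pd.DataFrame(truth_rows)


def simulate_study(config: SyntheticConfig | None = None,
                   out_dir: str | Path | None = None) -> StudyBundle:
    """Generate a full study bundle; optionally write it as CSVs.

    The on-disk layout matches the pipeline readers: ``combinations.csv``
    (long format), ``monotherapy.csv``, ``descriptors.csv``,
    ``annotations.csv``, ``truth.csv`` and one CSV per omics block under
    ``blocks/``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    descriptors, curves, arch_of = simulate_drugs(config, rng)
    blocks, annotations, cell_factor = simulate_cells(config, rng)
    matrices, truth = simulate_combinations(config, curves, cell_factor, rng)
    bundle = StudyBundle(config, descriptors, curves, arch_of, blocks,
                         annotations, cell_factor, matrices, truth)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: StudyBundle, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    combo_rows, mono_seen, mono_rows = [], set(), []
    for m in bundle.matrices:
        for d1, d2, y in zip(m.d1, m.d2, m.y):
            combo_rows.append((m.drug1_id, m.drug2_id, m.cell_id, d1, d2, y))
        for which, drug in ((1, m.drug1_id), (2, m.drug2_id)):
            if (drug, m.cell_id) not in mono_seen:
                mono_seen.add((drug, m.cell_id))
                doses, resp = m.mono1 if which == 1 else m.mono2
                mono_rows.extend((drug, m.cell_id, d, r) for d, r in zip(doses, resp))
    pd.DataFrame(combo_rows, columns=["drug1", "drug2", "cell", "conc1", "conc2",
                                      "response"]).to_csv(out / "combinations.csv",
                                                          index=False)
    pd.DataFrame(mono_rows, columns=["drug", "cell", "conc", "response"]
                 ).to_csv(out / "monotherapy.csv", index=False)
    bundle.descriptors.to_csv(out / "descriptors.csv")
    bundle.annotations.to_csv(out / "annotations.csv", index=False)
    bundle.truth.to_csv(out / "truth.csv", index=False)
    block_dir = out / "blocks"
    block_dir.mkdir(exist_ok=True)
    for name, df in bundle.blocks.items():
        df.to_csv(block_dir / f"{name}.csv")
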