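"""Omics missing-value policies, PCA reduction and hourglass autoencoders."""

import numpy as np
import pandas as pd
import pytest

from synerstack.omics_features import (BLOCK_ORDER, assemble_cell_profile,
                                       autoencoder_bottleneck_width,
                                       autoencoder_layer_widths,
                                       autoencoder_reduce, build_autoencoder,
                                       handle_missing, pca_reduce,
                                       standardize_block)


def make_block(n_cells=10, n_feat=8, seed=0, missing=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n_cells, n_feat)),
                      index=[f"c{i}" for i in range(n_cells)],
                      columns=[f"f{j}" for j in range(n_feat)])
    if missing:
        for r, c in missing:
            df.iloc[r, c] = np.nan
    return df


class TestMissing:
    def test_drop_sample_removes_incomplete_rows(self):
        block = make_block(missing=[(3, 2)])
        out = handle_missing(block, "drop_sample")
        assert len(out) == 9 and "c3" not in out.index

    def test_fill_zero_keeps_all_rows(self):
        block = make_block(missing=[(3, 2), (7, 0)])
        out = handle_missing(block, "fill_zero")
        assert len(out) == 10 and not out.isna().any().any()
        assert out.iloc[3, 2] == 0.0

    def test_identity_on_fully_observed_block(self):
        block = make_block()
        for policy in ("drop_sample", "fill_zero"):
            pd.testing.assert_frame_equal(handle_missing(block, policy), block)

    def test_all_rows_dropped_errors(self):
        block = make_block(n_cells=2, missing=[(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="dropped"):
            handle_missing(block, "drop_sample")


class TestPca:
    def test_rank_one_block_concentrates_variance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=12)
        X = np.outer(rng.normal(size=30), v) + rng.normal(0, 1e-3, (30, 12))
        blk = pd.DataFrame(X, index=[f"c{i}" for i in range(30)])
        red = pca_reduce(standardize_block(blk), 5, name="x")
        assert red.explained_variance[0] > 0.99

    def test_variance_fractions_nonincreasing_and_loadings_orthonormal(self):
        blk = standardize_block(make_block(30, 12, seed=2))
        red = pca_reduce(blk, 6, name="x")
        ev = red.explained_variance
        assert np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-9
        L = red.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-8)
        assert np.abs(red.scores.mean(axis=0)).max() < 1e-8

    def test_latent_factor_spectrum_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(50, 5))
        W = rng.normal(size=(5, 40))
        X = Z @ W + rng.normal(0, 0.1, (50, 40))
        blk = standardize_block(pd.DataFrame(X))
        red = pca_reduce(blk, 10, name="x")
        # oracle: eigenvalues of the covariance matrix
        evals = np.linalg.eigvalsh(np.cov(blk.to_numpy().T, ddof=1))[::-1]
        oracle_top5 = evals[:5].sum() / evals.sum()
        assert red.explained_variance[:5].sum() == pytest.approx(oracle_top5, abs=0.02)
        assert red.explained_variance[:5].sum() > 0.8

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="components"):
            pca_reduce(make_block(4, 8), 5)

    def test_sign_convention_fixed(self):
        blk = standardize_block(make_block(20, 6, seed=5))
        red = pca_reduce(blk, 3, name="x")
        for c in red.loadings.columns:
            col = red.loadings[c].to_numpy()
            assert col[np.abs(col).argmax()] > 0


class TestAutoencoder:
    def test_bottleneck_rule_boundaries(self):
        assert autoencoder_bottleneck_width(499) == 249
        assert autoencoder_bottleneck_width(500) == 50
        assert autoencoder_bottleneck_width(9_999) == 999
        assert autoencoder_bottleneck_width(10_000) == 200
        with pytest.raises(ValueError):
            autoencoder_bottleneck_width(1)

    def test_layer_widths_form_strict_hourglass(self):
        widths = autoencoder_layer_widths(42)
        assert len(widths) == 7
        assert widths[0] == widths[-1] == 42 and widths[3] == 21
        assert widths[0] > widths[1] > widths[2] > widths[3]
        assert widths[1:4] == widths[4:][::-1][1:][::-1] or widths == widths[::-1]

    def test_build_matches_sizing_rule(self):
        net = build_autoencoder(42, seed=0, epochs=1)
        assert net.layer_widths == autoencoder_layer_widths(42)
        assert len(net.layer_widths) == 7

    def test_training_reduces_reconstruction_error(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(100, 3))
        W = rng.normal(size=(3, 40))
        blk = standardize_block(pd.DataFrame(Z @ W + rng.normal(0, 0.05, (100, 40))))
        red = autoencoder_reduce(blk, seed=0, epochs=30, name="x")
        assert red.scores.shape == (100, 20)
        net = red.encoder
        assert net.loss_curve_[-1] < net.loss_curve_[0]

    def test_reduction_is_deterministic_under_seed(self):
        blk = standardize_block(make_block(20, 10, seed=6))
        a = autoencoder_reduce(blk, seed=7, epochs=5, name="x").scores
        b = autoencoder_reduce(blk, seed=7, epochs=5, name="x").scores
        pd.testing.assert_frame_equal(a, b)


class TestProfile:
    def _blocks(self, cells):
        rng = np.random.default_rng(0)
        return {name: pd.DataFrame(rng.normal(size=(len(cells), 2)),
                                   index=cells,
                                   columns=[f"{name}_r{j}" for j in range(2)])
                for name in BLOCK_ORDER}

    def test_concatenation_width_and_order(self):
        cells = [f"c{i}" for i in range(5)]
        ann = pd.DataFrame({"cell": cells, "tissue": ["t1", "t2"] * 2 + ["t1"]})
        prof = assemble_cell_profile(self._blocks(cells), ann)
        assert prof.shape == (5, 2 * 7 + 1)
        assert list(prof.columns[:2]) == ["expression_r0", "expression_r1"]

    def test_inner_join_drops_cells_absent_from_any_block(self):
        cells = [f"c{i}" for i in range(5)]
        blocks = self._blocks(cells)
        blocks["cnv"] = blocks["cnv"].drop(index="c2")
        ann = pd.DataFrame({"cell": cells, "tissue": "t1"})
        prof = assemble_cell_profile(blocks, ann)
        assert "c2" not in prof.index and len(prof) == 4

    def test_unknown_tissue_flagged_not_dropped(self):
        cells = ["c0", "c1"]
        blocks = {n: df.loc[cells] for n, df in self._blocks(cells + ["c2"]).items()}
        ann = pd.DataFrame({"cell": ["c0"], "tissue": ["t1"]})
        prof = assemble_cell_profile(blocks, ann)
        assert prof.loc["c1", "tissue"] == "unknown" and len(prof) == 2

    def test_missing_block_rejected(self):
        blocks = self._blocks(["c0", "c1"])
        blocks.pop("proteomics")
        with pytest.raises(ValueError, match="proteomics"):
            assemble_cell_profile(blocks, pd.DataFrame({"cell": [], "tissue": []}))
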