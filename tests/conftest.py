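import numpy as np
import pytest

from synerstack.pipeline import PipelineConfig, run_study
from synerstack.synthetic_data import SyntheticConfig, simulate_study

STUDY_SEED = 3


@pytest.fixture(scope="session")
def study_bundle():
    """Default desk-scale synthetic study: 20 drugs, 12 cells, 600 matrices."""
    return simulate_study(SyntheticConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def pipeline_result(study_bundle):
    """Full pipeline run (scoring, labeling, features, splits, learners)."""
    import time
    t0 = time.monotonic()
    result = run_study(study_bundle, seed=STUDY_SEED)
    result.wall_seconds = time.monotonic() - t0
    return result


@pytest.fixture(scope="session")
def cell_driven_result():
    """Study whose synergy offset depends only on the expression block's
    latent factor, with a cell panel wide enough that cell identity cannot
    be memorized through every block; for feature-contribution checks."""
    cfg = SyntheticConfig(seed=STUDY_SEED + 1, n_pairs=16, n_cells=40,
                          n_tissues=4, n_descriptors=10,
                          delta_mode="cell_only")
    bundle = simulate_study(cfg)
    result = run_study(bundle, seed=STUDY_SEED + 1, config=PipelineConfig(
        score_models=("bliss", "hsa", "loewe", "zip")))
    return bundle, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
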