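"""End-to-end orchestration: score -> label -> featurize -> split -> learn.

Runs the whole method on an in-memory study bundle at desk scale: synergy
scoring under the five reference models, full-agreement labeling, drug and
omics feature preparation, hold-out construction, base-learner training,
prediction-space stacking and metric reporting.  Defaults are sized for a
small synthetic study (hundreds of matrices, a dozen cell lines); every
knob scales up for larger inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dataset_assembly, drug_features, ensemble_stack, evaluation_interpret
from . import labeling, learners, omics_features, reference_models
from .synthetic_data import StudyBundle

__all__ = ["PipelineConfig", "PipelineResult", "run_study", "feature_contribution"]

# Fixed desk-scale hyperparameters per family (grid search is available via
# learners.grid_search when the training set is large enough to subsample).
_BASE_CONFIGS = {
    "random_forest": {"n_estimators": 200},
    "extremely_randomized_trees": {"n_estimators": 200},
    "gradient_boosted_trees": {"max_depth": 3, "n_estimators": 200},
    "k_nearest_neighbors": {"n_neighbors": 5, "weights": "distance"},
    "support_vector_machine": {"C": 1.0, "kernel": "rbf"},
    "linear_sgd": {"alpha": 1e-3},
    "feedforward_net": {"architecture": [32, 32], "dropout": 0.0,
                        "learning_rate": 1e-3, "epochs": 200, "batch_size": 16},
}


@dataclass
class PipelineConfig:
    score_models: tuple = ("bliss", "hsa", "loewe", "zip", "css")
    n_components: int = 5          # per-block PCs at desk scale (25 at full scale)
    missing_policy: str = "fill_zero"
    regression_target: str = "score_bliss"
    n_drug_clusters: int = 5
    # stacker settings: small-sample schedule keeping the total number of
    # Adam updates within range of the large-sample reference recipe
    stacker_hidden: tuple = (16,)
    stacker_dropout: float = 0.0
    stacker_lr: float = 1e-3
    stacker_epochs: int = 300
    stacker_batch: int = 16
    base_families: tuple = tuple(_BASE_CONFIGS)


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    labels: pd.DataFrame
    dataset: dataset_assembly.AssembledDataset
    plan: dataset_assembly.SplitPlan
    reduced_blocks: dict
    base_models: dict = field(default_factory=dict)       # task -> {family: model}
    ensembles: dict = field(default_factory=dict)         # task -> EnsembleModel
    report: dict = field(default_factory=dict)

    def column_block(self, col: str) -> str:
        """Feature block of an assembled input column (drug or omics block)."""
        if col.startswith(("d1_", "d2_")):
            return "drug"
        if col.startswith("cell_"):
            return col[len("cell_"):].rsplit("_", 1)[0]
        raise KeyError(f"not an assembled feature column: {col!r}")


def _prepare_features(bundle: StudyBundle, config: PipelineConfig):
    desc_filtered, _ = drug_features.filter_descriptors(bundle.descriptors)
    desc_std, _ = drug_features.standardize(desc_filtered)
    reduced = {}
    for name, block in bundle.blocks.items():
        std = omics_features.standardize_block(block)
        std = omics_features.handle_missing(std, config.missing_policy)
        reduced[name] = omics_features.pca_reduce(std, config.n_components, name=name)
    profile = omics_features.assemble_cell_profile(reduced, bundle.annotations)
    return desc_std, reduced, profile


def _evaluate(models: dict, ensemble, dataset, target, task, threshold=0.5):
    table = dataset.table
    report = {}
    for tag in dataset_assembly.SPLIT_TAGS:
        rows = table[table["split"] == tag]
        if task == "classification":
            rows = rows[rows["agreement_label"] != labeling.DROPPED]
        if rows.empty:
            continue
        X = rows[dataset.feature_cols].to_numpy(float)
        y = _task_target(rows, target, task)
        for name, model in models.items():
            pred = learners.predict(model, X)
            report.setdefault(name, {})[tag] = _metrics(y, pred, task, threshold)
        if ensemble is not None:
            pred = ensemble_stack.predict_ensemble(ensemble, X)
            report.setdefault("ensemble", {})[tag] = _metrics(y, pred, task, threshold)
    return report


def _metrics(y, pred, task, threshold):
    if task == "classification":
        return evaluation_interpret.classification_metrics(y, pred, threshold)
    return evaluation_interpret.regression_metrics(y, pred)


def _task_target(rows, target, task):
    if task == "classification":
        return (rows["agreement_label"] == labeling.SYNERGISTIC).to_numpy(int)
    return rows[target].to_numpy(float)


def _fit_task(dataset, target, task, config: PipelineConfig, seed: int):
    train = dataset.rows("train")
    if task == "classification":
        train = train[train["agreement_label"] != labeling.DROPPED]
        y = _task_target(train, target, task)
        if len(np.unique(y)) < 2 or min(np.bincount(y)) < 5:
            return None, None, "skipped: fewer than 2 usable classes in training rows"
    else:
        y = _task_target(train, target, task)
    X = train[dataset.feature_cols].to_numpy(float)

    models = {}
    for i, family in enumerate(config.base_families):
        mc = learners.ModelConfig(family, task, dict(_BASE_CONFIGS[family]))
        models[family] = learners.train_model(mc, X, y, seed=seed + i)
    meta = ensemble_stack.build_meta_features(
        {f: learners.predict(m, X) for f, m in models.items()})
    stacker = ensemble_stack.train_stacker(
        meta, y, task,
        hidden=config.stacker_hidden, dropout=config.stacker_dropout,
        learning_rate=config.stacker_lr, epochs=config.stacker_epochs,
        batch_size=config.stacker_batch, seed=seed + 100)
    ensemble = ensemble_stack.EnsembleModel(stacker, list(models.values()),
                                            task, list(models))
    return models, ensemble, None


def run_study(bundle: StudyBundle, seed: int = 0,
              config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full method on a study bundle and return models + report."""
    config = config or PipelineConfig()
    scores = reference_models.score_table(bundle.matrices,
                                          models=config.score_models)
    labels = labeling.label_table(scores)
    desc_std, reduced, profile = _prepare_features(bundle, config)
    dataset = dataset_assembly.join_features(scores, labels, desc_std, profile)
    clusters = dataset_assembly.cluster_drugs(desc_std, config.n_drug_clusters)
    plan = dataset_assembly.make_holdouts(dataset, bundle.annotations, clusters, seed)

    result = PipelineResult(scores=scores, labels=labels, dataset=dataset,
                            plan=plan, reduced_blocks=reduced)
    for task, target in (("regression", config.regression_target),
                         ("classification", None)):
        models, ensemble, note = _fit_task(dataset, target, task, config, seed)
        if note is not None:
            result.report[task] = {"note": note}
            continue
        result.base_models[task] = models
        result.ensembles[task] = ensemble
        result.report[task] = _evaluate(models, ensemble, dataset, target, task)
    return result


def feature_contribution(result: PipelineResult, *, task: str = "regression",
                         model: str = "ensemble", tag: str = "test",
                         repeats: int = 10, seed: int = 0) -> dict:
    """Two-stage contribution analysis on held-out rows.

    Stage 1: permutation importance of every assembled input column.
    Stage 2: PCA-reduced cell columns propagate to original omics features
    through squared loadings.  Returns per-column importances, per-original-
    feature weights and percent block shares (drug descriptors as one block,
    each omics block separately).
    """
    dataset = result.dataset
    rows = dataset.rows(tag)
    if task == "classification":
        rows = rows[rows["agreement_label"] != labeling.DROPPED]
    X = rows[dataset.feature_cols].to_numpy(float)
    if task == "regression":
        y = rows[PipelineConfig().regression_target].to_numpy(float)
        metric = lambda t, p: evaluation_interpret.regression_metrics(t, p)["rmse"]
        maximize = False
    else:
        y = (rows["agreement_label"] == labeling.SYNERGISTIC).to_numpy(int)
        metric = lambda t, p: evaluation_interpret.classification_metrics(t, p)["accuracy"]
        maximize = True
    if model == "ensemble":
        ens = result.ensembles[task]
        predict_fn = lambda M: ensemble_stack.predict_ensemble(ens, M)
    else:
        mdl = result.base_models[task][model]
        predict_fn = lambda M: learners.predict(mdl, M)
    imp = evaluation_interpret.permutation_importance(
        predict_fn, X, y, metric, repeats=repeats, seed=seed, maximize=maximize)
    importances = pd.Series(imp, index=dataset.feature_cols)

    feature_weights = {}
    for name, blk in result.reduced_blocks.items():
        cols = [f"cell_{c}" for c in blk.scores.columns]
        comp_imp = importances.reindex(cols).fillna(0.0).to_numpy()
        weights = evaluation_interpret.propagate_pca_importance(comp_imp, blk.loadings)
        feature_weights[name] = weights

    shares = evaluation_interpret.block_share(
        importances, {c: result.column_block(c) for c in importances.index})
    return {"column_importance": importances, "feature_weights": feature_weights,
            "block_share": shares}
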