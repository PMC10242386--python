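"""End-to-end discovery and training pipeline.

Order of stages: low-variation filter -> voom -> stratified split ->
stage-indicator and ordinal models (on the training samples) ->
consensus of the two top-n rankings -> Boruta -> RFE -> iterative VIF
elimination -> PCA with reconciled component count -> silhouette check of
k -> k = 2 k-means classifier -> 5-fold cross-validation on the training
set -> held-out test-set evaluation.  Every stage logs its input/output
dimensions; any stage failure is re-raised as a :class:`StageError`
naming the stage.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import feature_select, pc_cluster, preprocess, stage_models
from .cohort import CohortConfig  # noqa: F401  (re-exported for callers)
from .config import PipelineConfig
from .containers import ExpressionMatrix, StageDesign
from .errors import StagemarkError, StageError
from .metrics import ConfusionCounts, MetricsRecord, compute_metrics

log = logging.getLogger("stagemark")


@dataclass
class PipelineResult:
    config: PipelineConfig
    removed_low_variance: list[str]
    split: preprocess.SplitIndex
    stat_table: pd.DataFrame = field(repr=False)
    consensus: list[str]
    boruta: feature_select.BorutaResult
    rfe_kept: list[str]
    vif_report: feature_select.VIFReport
    panel: list[str]
    pca: pc_cluster.PCAModel
    criteria: pc_cluster.PcCountCriteria
    silhouette_k: int
    classifier: pc_cluster.KMeansClassifier
    metrics: dict[str, MetricsRecord]
    stage_sizes: dict[str, int]


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except StagemarkError:
        raise
    except Exception as exc:
        raise StageError(name, exc) from exc
    log.info("stage %s: done", name)


def run_pipeline(
    config: PipelineConfig, expr: ExpressionMatrix, design: StageDesign
) -> PipelineResult:
    """Run discovery + training + evaluation; fully reproducible given the seed."""
    config.validate()
    sizes: dict[str, int] = {}

    with _stage("filter"):
        filtered, removed = preprocess.filter_low_variance(expr, config.filter_threshold)
        sizes["filter"] = filtered.n_genes
        log.info("filter: %d genes kept, %d removed", filtered.n_genes, len(removed))

    with _stage("voom"):
        voom = preprocess.voom_transform(filtered)

    with _stage("split"):
        split = preprocess.stratified_split(design, config.split_ratio, config.seed)
        log.info("split: %d train / %d test", len(split.train_ids), len(split.test_ids))

    train_design = design.subset(split.train_ids)
    voom_train = voom.subset_samples(split.train_ids)

    with _stage("stage_models"):
        linear = stage_models.fit_linear_stage_model(voom_train, train_design)
        ordinal = stage_models.fit_ordinal_model(voom_train, train_design)
        table = stage_models.build_stat_table(
            stage_models.moderate_linear(linear), stage_models.moderate_ordinal(ordinal)
        )

    with _stage("consensus"):
        consensus = stage_models.rank_and_consensus(table, config.top_n, config.adjp_threshold)
        sizes["consensus"] = len(consensus)
        log.info("consensus: %d genes", len(consensus))
        if len(consensus) < 2:
            raise StageError("consensus", ValueError(
                f"only {len(consensus)} consensus genes at adj. p < {config.adjp_threshold}"
            ))

    x_train = voom_train.log_cpm.loc[consensus].T
    y_train = train_design.classes.loc[list(split.train_ids)].to_numpy()

    with _stage("boruta"):
        boruta = feature_select.boruta_select(x_train, y_train, seed=config.seed)
        sizes["boruta"] = len(boruta.confirmed)
        log.info("boruta: %d confirmed of %d", len(boruta.confirmed), len(consensus))
        if len(boruta.confirmed) < 2:
            raise StageError("boruta", ValueError("fewer than 2 confirmed features"))

    with _stage("rfe"):
        rfe_kept = feature_select.rfe_select(
            x_train[boruta.confirmed], y_train, folds=config.folds, seed=config.seed
        )
        sizes["rfe"] = len(rfe_kept)
        log.info("rfe: %d kept", len(rfe_kept))

    with _stage("vif"):
        vif_report = feature_select.vif_eliminate(x_train[rfe_kept], config.vif_threshold)
        panel = vif_report.kept
        sizes["vif"] = len(panel)
        log.info("vif: %d in final panel (removed %s)", len(panel), vif_report.removed)

    with _stage("pca"):
        pca = pc_cluster.fit_pca(x_train[panel])
        criteria = pc_cluster.pc_count_criteria(pca.eigenvalues, config.var_threshold)
        pca = pca.with_components(criteria.reconciled)
        log.info("pca: criteria %s -> q = %d", criteria, pca.q)

    scores_train = pca.transform(x_train[panel])

    with _stage("silhouette"):
        k_range = range(config.k_min, min(config.k_max, len(split.train_ids) - 1) + 1)
        silhouette_k = pc_cluster.silhouette_optimal_k(scores_train, k_range, config.seed)
        log.info("silhouette: optimal k = %d", silhouette_k)

    with _stage("classifier"):
        clf = pc_cluster.fit_classifier(scores_train, y_train, k=2, seed=config.seed)

    with _stage("cross_validation"):
        cv = pc_cluster.cross_validate(
            x_train[panel], y_train,
            folds=config.folds, seed=config.seed, var_threshold=config.var_threshold,
        )

    with _stage("test_evaluation"):
        x_test = voom.log_cpm.loc[panel, list(split.test_ids)].T
        y_test = design.classes.loc[list(split.test_ids)].to_numpy()
        classes, margin = pc_cluster.classify_scores(clf, pca.transform(x_test))
        test_metrics = compute_metrics(
            ConfusionCounts.from_labels(y_test, classes), margin, y_test
        )
        train_classes, train_margin = pc_cluster.classify_scores(clf, scores_train)
        train_metrics = compute_metrics(
            ConfusionCounts.from_labels(y_train, train_classes), train_margin, y_train
        )

    return PipelineResult(
        config=config,
        removed_low_variance=removed,
        split=split,
        stat_table=table,
        consensus=consensus,
        boruta=boruta,
        rfe_kept=rfe_kept,
        vif_report=vif_report,
        panel=panel,
        pca=pca,
        criteria=criteria,
        silhouette_k=silhouette_k,
        classifier=clf,
        metrics={"train": train_metrics, "train_cv": cv["pooled"], "test": test_metrics},
        stage_sizes=sizes,
    )
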