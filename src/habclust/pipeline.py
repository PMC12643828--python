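"""End-to-end convenience wrappers tying the stages together."""

from __future__ import annotations

import logging

import numpy as np

from .embedding import (
    ClusterModel,
    FeatureTable,
    extract_feature_tables,
    order_clusters,
    select_k,
)
from .io_formats import RunConfig, SpikeTrain
from .matching import MatchResult, match_clusters

logger = logging.getLogger("habclust")


def cluster_dataset(
    trains: list[SpikeTrain], config: RunConfig | None = None
) -> tuple[FeatureTable, ClusterModel]:
    """Features -> embedding -> BIC-selected mixture -> rate-ordered labels."""
    cfg = config or RunConfig()
    logger.info("cluster_dataset: config %s, %d neurons", cfg.config_hash(), len(trains))
    (table,) = extract_feature_tables([trains], cfg)
    model = select_k(
        table,
        k_grid=tuple(range(cfg.k_min, cfg.k_max + 1)),
        n_restarts=cfg.n_restarts,
        seed=cfg.seed,
        covariance_type=cfg.covariance_type,
        reg_covar=cfg.reg_covar,
        saturation_frac=cfg.saturation_frac,
    )
    return table, order_clusters(model, table)


def cluster_and_match(
    trains_a: list[SpikeTrain],
    trains_b: list[SpikeTrain],
    config: RunConfig | None = None,
) -> tuple[FeatureTable, FeatureTable, ClusterModel, ClusterModel, MatchResult]:
    """Cluster two datasets in a shared feature space and match clusters.

    The sparse-PCA banks and feature standardization are fitted on the
    pooled neurons so both models' centroids live on common axes; the
    mixtures themselves are fitted separately per dataset.
    """
    cfg = config or RunConfig()
    table_a, table_b = extract_feature_tables([trains_a, trains_b], cfg)
    kwargs = dict(
        k_grid=tuple(range(cfg.k_min, cfg.k_max + 1)),
        n_restarts=cfg.n_restarts,
        covariance_type=cfg.covariance_type,
        reg_covar=cfg.reg_covar,
        saturation_frac=cfg.saturation_frac,
    )
    model_a = order_clusters(select_k(table_a, seed=cfg.seed, **kwargs), table_a)
    model_b = order_clusters(select_k(table_b, seed=cfg.seed + 1, **kwargs), table_b)
    match = match_clusters(model_a, model_b, threshold=cfg.similarity_threshold)
    return table_a, table_b, model_a, model_b, match


def labels_aligned(model: ClusterModel, neuron_ids: list[str]) -> np.ndarray:
    """Model labels reordered to an external neuron-id ordering."""
    lut = dict(zip(model.neuron_ids, model.labels))
    return np.asarray([lut[i] for i in neuron_ids])
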