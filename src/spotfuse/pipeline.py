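"""End-to-end orchestration: preprocess -> histology features -> spatial
graph -> contrastive graph auto-encoder -> clustering -> scores."""

from __future__ import annotations

import dataclasses
import logging
import time
from typing import Optional

import numpy as np

from .cluster import ClusterResult, cluster_embeddings, refine_labels, score
from .data import RunConfig, SpotDataset
from .graph import SpatialGraph, build_graph
from .histology import crop_spots, hvit_encode, pca_reduce
from .model import GclModel, LossReport, train
from .preprocess import preprocess_expression

log = logging.getLogger("spotfuse")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclasses.dataclass
class PipelineResult:
    X: np.ndarray
    I: Optional[np.ndarray]
    graph: SpatialGraph
    model: GclModel
    H: np.ndarray
    report: LossReport
    clusters: Optional[ClusterResult]
    labels: Optional[np.ndarray]
    ari: Optional[float] = None
    nmi: Optional[float] = None


def run_pipeline(
    dataset: SpotDataset,
    config: RunConfig,
    image=None,
    use_image: bool = True,
    graph: Optional[SpatialGraph] = None,
    epochs: Optional[int] = None,
) -> PipelineResult:
    """Run the full analysis on one slice (or a pre-aligned stack).

    ``image`` may be an array or a path; when absent (or ``use_image`` is
    off) the model runs in expression-only mode.  A pre-built ``graph``
    (e.g. a cross-slice graph) overrides the per-slice radius graph.
    Clustering uses ``config.n_clusters`` when given, otherwise Louvain.
    """
    t0 = time.time()
    expr = preprocess_expression(
        dataset,
        n_hvg=config.n_hvg,
        log_before_norm=config.log_before_norm,
        scale_clip=config.scale_clip,
    )
    X = expr.X

    I = None
    if use_image:
        img = image
        if img is None and dataset.image_path is not None:
            img = dataset.image_path
        if img is not None:
            crops = crop_spots(img, dataset.coords, h=config.crop_size)
            feats = hvit_encode(
                crops,
                patch_size=config.patch_size,
                heads=config.vit_heads,
                layers=config.vit_layers,
                seed=config.seed,
            )
            I = pca_reduce(feats, k=config.n_image_pcs).I

    if graph is None:
        graph = build_graph(
            dataset.coords, radius=config.radius, spacing=dataset.spot_spacing
        )

    model, H, report = train(X, I, graph, config, epochs=epochs)

    clusters = None
    labels = None
    if config.n_clusters is not None or config.clusterer == "louvain":
        clusters = cluster_embeddings(
            H,
            method=config.clusterer,
            n_clusters=config.n_clusters,
            resolution=config.resolution,
            seed=config.seed,
        )
        labels = clusters.labels
        if config.refine:
            labels = refine_labels(labels, dataset.coords, config.refine_k)
            clusters = dataclasses.replace(clusters, labels=labels, refined=True)

    ari = nmi = None
    if labels is not None and dataset.labels is not None:
        ari, nmi = score(labels, dataset.labels)
        log.info("pipeline: ARI=%.4f NMI=%.4f", ari, nmi)
    log.info("pipeline done in %.1fs (seed=%d)", time.time() - t0, config.seed)
    return PipelineResult(
        X=X, I=I, graph=graph, model=model, H=H, report=report,
        clusters=clusters, labels=labels, ari=ari, nmi=nmi,
    )
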