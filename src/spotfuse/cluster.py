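"""Spatial-domain clustering of the joint embedding, spatial label
refinement, optimal label matching and agreement scores.

With a known number of domains a seeded Gaussian mixture (the Python
counterpart of model-based clustering) is used; without one, Louvain
community detection on a shared-nearest-neighbor graph, tuned by a
resolution parameter.  Refinement reassigns each spot to the modal label of
its k spatially nearest neighbors (synchronous update; ties keep the
current label) and is meant for spatial-domain, not cell-type, outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger("spotfuse")

__all__ = [
    "ClusterResult",
    "cluster_embeddings",
    "refine_labels",
    "match_labels",
    "score",
    "project_umap",
]


@dataclasses.dataclass
class ClusterResult:
    labels: np.ndarray  # contiguous integer ids from 0
    method: str
    n_clusters: Optional[int] = None
    resolution: Optional[float] = None
    refined: bool = False


def _contiguous(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(int)


def cluster_embeddings(
    H: np.ndarray,
    method: str = "gmm",
    n_clusters: Optional[int] = None,
    resolution: float = 1.0,
    seed: int = 0,
    knn: int = 15,
) -> ClusterResult:
    """Cluster spots in embedding space.

    ``method="gmm"``: full-covariance Gaussian mixture with ``n_clusters``
    components, seeded k-means initialization and multiple restarts.
    ``method="louvain"``: Louvain communities on a shared-nearest-neighbor
    graph (Jaccard-weighted kNN) at the given resolution.
    """
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("embedding contains non-finite values")
    n = H.shape[0]
    if method == "gmm":
        if n_clusters is None:
            raise ValueError("gmm clustering needs n_clusters")
        if n_clusters > n:
            raise ValueError(f"n_clusters {n_clusters} exceeds n spots {n}")
        if n_clusters == n:
            labels = np.arange(n)
        else:
            gm = GaussianMixture(
                n_components=n_clusters,
                covariance_type="full",
                n_init=5,
                reg_covar=1e-4,
                random_state=seed,
                max_iter=300,
            )
            labels = gm.fit_predict(H)
        res = ClusterResult(_contiguous(labels), "gmm", n_clusters=n_clusters)
    elif method == "louvain":
        labels = _louvain(H, resolution=resolution, seed=seed, knn=knn)
        res = ClusterResult(_contiguous(labels), "louvain", resolution=resolution)
    else:
        raise ValueError("method must be 'gmm' or 'louvain'")
    log.info(
        "cluster_embeddings[%s]: n=%d -> %d clusters",
        method, n, len(np.unique(res.labels)),
    )
    return res


def _louvain(H: np.ndarray, resolution: float, seed: int, knn: int) -> np.ndarray:
    import igraph as ig

    n = H.shape[0]
    k = min(knn + 1, n)
    nn = NearestNeighbors(n_neighbors=k).fit(H)
    _, idx = nn.kneighbors(H)
    neigh = [set(row[1:]) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i][1:]:
            if j > i:
                shared = len(neigh[i] & neigh[int(j)])
                union = len(neigh[i] | neigh[int(j)])
                w = shared / union if union else 0.0
                if w > 0:
                    edges.append((i, int(j)))
                    weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    import random

    random.seed(seed)
    ig.set_random_number_generator(random)
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return np.asarray(part.membership)


def refine_labels(
    labels: Sequence, coords: np.ndarray, k_neighbors: int = 50
) -> np.ndarray:
    """Majority vote of each spot's k spatially nearest neighbors.

    All votes are computed from the pre-refinement labels (synchronous
    update); the spot itself does not vote, and a tie in the modal label
    keeps the current one.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, dtype=float)
    n = len(labels)
    if coords.shape[0] != n:
        raise ValueError("labels and coords must be row-aligned")
    if k_neighbors < 1 or n < 2:
        return labels.copy()
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    cats, codes = np.unique(labels, return_inverse=True)
    out = codes.copy()
    for i in range(n):
        votes = np.bincount(codes[idx[i, 1 : k + 1]], minlength=len(cats))
        top = np.flatnonzero(votes == votes.max())
        if len(top) == 1:
            out[i] = top[0]
        # tie -> keep current label
    return cats[out]


def match_labels(pred: Sequence, truth: Sequence) -> tuple[dict, np.ndarray]:
    """Optimal one-to-one mapping of predicted onto true categories.

    Solves the assignment problem on the contingency table (Kuhn-Munkres),
    maximizing total agreement.  Surplus predicted categories map to fresh
    ids beyond the true ones.  Returns ``(mapping, matched_labels)`` where
    ``matched_labels`` is ``pred`` rewritten through the mapping.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) == 0 or len(pred) != len(truth):
        raise ValueError("pred and truth must be equal-length and non-empty")
    pcats, pcodes = np.unique(pred, return_inverse=True)
    tcats, tcodes = np.unique(truth, return_inverse=True)
    cont = np.zeros((len(pcats), len(tcats)))
    np.add.at(cont, (pcodes, tcodes), 1)
    rows, cols = linear_sum_assignment(-cont)
    mapping: dict = {}
    fresh = len(tcats)
    assigned = dict(zip(rows.tolist(), cols.tolist()))
    for pi in range(len(pcats)):
        if pi in assigned:
            mapping[pcats[pi]] = tcats[assigned[pi]]
        else:
            mapping[pcats[pi]] = fresh
            fresh += 1
    matched = np.asarray([mapping[p] for p in pred])
    return mapping, matched


def score(pred: Sequence, truth: Sequence) -> tuple[float, float]:
    """(ARI, NMI) of the predicted partition against the truth.

    ARI is the permutation-model adjusted Rand index; NMI uses
    arithmetic-mean normalization.  Both are invariant to label renaming.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must be equal length")
    ari = metrics.adjusted_rand_score(truth, pred)
    nmi = metrics.normalized_mutual_info_score(truth, pred, average_method="arithmetic")
    return float(ari), float(nmi)


def project_umap(H: np.ndarray, seed: int = 0) -> np.ndarray:
    """Seeded 2D UMAP projection of the embedding, for plotting only."""
    import umap

    H = np.asarray(H, dtype=float)
    if H.shape[0] < 3:
        raise ValueError("UMAP projection needs at least 3 points")
    reducer = umap.UMAP(n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(H), dtype=float)
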