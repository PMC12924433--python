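"""Expression preprocessing: library-size normalization, log transform,
highly-variable-gene selection and per-gene standardization.

The default pipeline is normalize -> log1p -> HVG -> scale; the alternative
order with the log transform first is selectable via ``log_before_norm``.
HVG ranking uses a Seurat-style mean-binned normalized dispersion with a
deterministic tie-break by ascending gene index.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import scanpy as sc
from anndata import AnnData

from .data import SpotDataset

log = logging.getLogger("spotfuse")

__all__ = ["ExpressionMatrix", "preprocess_expression", "select_hvg", "scale_columns"]


@dataclasses.dataclass
class ExpressionMatrix:
    """Initialized expression features X (n spots x f1 genes) plus provenance."""

    X: np.ndarray
    gene_ids: list[str]
    transform_log: list[dict]


def normalized_dispersion(X: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Seurat-flavor dispersion: var/mean per gene, z-scored within mean bins.

    Genes with zero mean get dispersion -inf so they rank last.  Bins with a
    single gene (z-score undefined) fall back to the raw dispersion.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), -np.inf)
    finite = np.isfinite(disp)
    if finite.sum() == 0:
        return disp
    qs = np.quantile(mean[finite], np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    bins = np.clip(np.searchsorted(edges, mean, side="left") - 1, 0, len(edges) - 2)
    out = np.full_like(disp, -np.inf)
    for b in np.unique(bins[finite]):
        idx = finite & (bins == b)
        vals = disp[idx]
        sd = vals.std()
        if idx.sum() > 1 and sd > 0:
            out[idx] = (vals - vals.mean()) / sd
        else:
            out[idx] = vals
    return out


def select_hvg(X_norm: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most variable genes of a normalized, log-scaled matrix.

    Ranking is by descending normalized dispersion; exact ties are broken by
    ascending gene index.  Returns the selected indices sorted ascending.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X_norm = np.asarray(X_norm, dtype=float)
    g = X_norm.shape[1]
    k = min(k, g)
    disp = normalized_dispersion(X_norm)
    # stable sort on (-dispersion, index) => ties resolved by lower index
    order = np.lexsort((np.arange(g), -disp))
    return np.sort(order[:k])


def scale_columns(
    X: np.ndarray, clip: float | None = None, eps: float = 1e-12
) -> np.ndarray:
    """Standardize each column to mean 0, variance 1 (population variance).

    Constant columns are centered only.  Idempotent up to floating error.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std_safe = np.where(std > eps, std, 1.0)
    Z = (X - mean) / std_safe
    if clip is not None:
        Z = np.clip(Z, -clip, clip)
    return Z


def preprocess_expression(
    dataset: SpotDataset,
    n_hvg: int = 3000,
    log_before_norm: bool = False,
    scale_clip: float | None = None,
) -> ExpressionMatrix:
    """Raw counts -> initialized expression matrix X.

    Steps: library-size normalization (median total), log1p, top
    ``min(n_hvg, g)`` HVGs by normalized dispersion, then per-gene scaling to
    zero mean / unit variance.  All-zero spots are kept (with a warning) and
    contribute a zero row before scaling.
    """
    if dataset.n_genes == 0:
        raise ValueError("dataset has no genes")
    if dataset.n_spots < 2:
        raise ValueError("preprocessing needs at least 2 spots")
    counts = dataset.counts_dense()
    zero_rows = int((counts.sum(axis=1) == 0).sum())
    if zero_rows:
        warnings.warn(f"{zero_rows} spots have zero total counts; retained")

    steps: list[dict] = []
    adata = AnnData(counts.copy())
    if log_before_norm:
        sc.pp.log1p(adata)
        steps.append({"step": "log1p"})
        sc.pp.normalize_total(adata)
        steps.append({"step": "normalize_total", "target_sum": "median"})
    else:
        sc.pp.normalize_total(adata)
        steps.append({"step": "normalize_total", "target_sum": "median"})
        sc.pp.log1p(adata)
        steps.append({"step": "log1p"})
    Xn = np.asarray(adata.X, dtype=float)

    idx = select_hvg(Xn, n_hvg)
    steps.append({"step": "hvg", "n_requested": n_hvg, "n_selected": int(len(idx))})
    Xh = Xn[:, idx]
    Xs = scale_columns(Xh, clip=scale_clip)
    steps.append({"step": "scale", "clip": scale_clip})
    log.info(
        "preprocess_expression: %d spots, %d/%d genes retained",
        dataset.n_spots, len(idx), dataset.n_genes,
    )
    return ExpressionMatrix(
        X=Xs,
        gene_ids=[dataset.gene_ids[i] for i in idx],
        transform_log=steps,
    )
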