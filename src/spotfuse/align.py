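"""Multi-slice 3D reconstruction: translation-only alignment of serial
(vertical) or adjacent (horizontal) tissue slices and the cross-slice
neighborhood graph.

Vertical mode treats every spot as part of the cut surface, aligns each
slice's centroid to the reference slice (slice 1, never moved) and assigns
z-coordinates z_1 = 0, z_i = (i-1) * d + lambda * sum_{j<i} l_{j,j+1},
where d is the slice thickness and l the inter-slice separations (microns).
Horizontal mode abuts the right slice against the left one using the edge
spots of the cutting surface.  The method is pure translation — it assumes
consecutive cut surfaces are nearly identical in shape and size.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from .data import SpotDataset
from .graph import SpatialGraph, build_graph

log = logging.getLogger("spotfuse")

__all__ = [
    "SliceStack",
    "edge_spots",
    "align_vertical",
    "align_horizontal",
    "cross_slice_graph",
    "stack_z_coordinates",
]


@dataclasses.dataclass
class SliceStack:
    """An ordered set of slices plus the geometry of their 3D arrangement."""

    slices: list[SpotDataset]
    mode: str = "vertical"  # {"vertical", "horizontal"}
    thickness: float = 10.0  # slice thickness d, microns
    separations: Optional[Sequence[float]] = None  # l_{j,j+1}, microns
    lam: float = 1.0  # scale on the separation term
    z_unit_scale: float = 1.0  # microns -> coordinate units
    aligned_coords: Optional[np.ndarray] = None  # (sum n_i) x 3

    def __post_init__(self) -> None:
        if self.mode not in ("vertical", "horizontal"):
            raise ValueError("mode must be 'vertical' or 'horizontal'")
        s = len(self.slices)
        if self.separations is None:
            self.separations = [0.0] * max(s - 1, 0)
        if len(self.separations) != max(s - 1, 0):
            raise ValueError("need one separation per consecutive slice pair")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")

    @property
    def n_total(self) -> int:
        return sum(d.n_spots for d in self.slices)

    def slice_offsets(self) -> np.ndarray:
        return np.cumsum([0] + [d.n_spots for d in self.slices])

    def write_aligned_csv(self, path) -> None:
        if self.aligned_coords is None:
            raise ValueError("stack is not aligned yet")
        import pandas as pd

        rows = []
        k = 0
        for ds in self.slices:
            for sid in ds.spot_ids:
                rows.append((sid, ds.slice_id, *self.aligned_coords[k]))
                k += 1
        pd.DataFrame(
            rows, columns=["spot_id", "slice_id", "x", "y", "z"]
        ).to_csv(path, index=False)


def stack_z_coordinates(
    s: int, thickness: float, lam: float, separations: Sequence[float]
) -> np.ndarray:
    """z for each of s slices: 0 for the first, then the thickness/separation sum."""
    z = np.zeros(s)
    for i in range(2, s + 1):
        z[i - 1] = (i - 1) * thickness + lam * float(np.sum(separations[: i - 1]))
    return z


def edge_spots(
    dataset: SpotDataset,
    mode: str = "vertical",
    side: str = "all",
    tol: Optional[float] = None,
) -> np.ndarray:
    """Indices of the spots on the cut-surface edge structure.

    Vertical sectioning cuts through the whole slice, so every spot lies on
    the cut surface (``side="all"``).  Horizontal sectioning uses the
    rightmost ("right") or leftmost ("left") column of spots, within ``tol``
    (default: one spot spacing) of the extreme x.
    """
    if dataset.n_spots < 1:
        raise ValueError("dataset has no spots")
    x = dataset.coords[:, 0]
    if mode == "vertical" or side == "all":
        return np.arange(dataset.n_spots)
    if tol is None:
        tol = dataset.spot_spacing or 1.0
    if side == "right":
        idx = np.nonzero(x >= x.max() - tol)[0]
    elif side == "left":
        idx = np.nonzero(x <= x.min() + tol)[0]
    else:
        raise ValueError("side must be 'left', 'right' or 'all'")
    assert idx.size > 0, "edge structure cannot be empty for n >= 1"
    return idx


def align_vertical(stack: SliceStack) -> SliceStack:
    """Center-align every slice to slice 1 and assign z per the stacking rule.

    For each slice the center of its edge structure (here: all spots) is the
    coordinate mean; the bias to slice 1's center is subtracted.  Slice 1 is
    left untouched.  Populates ``stack.aligned_coords`` with x, y in the
    slices' native units and z in ``z_unit_scale``-scaled coordinate units.
    """
    if len(stack.slices) < 2:
        raise ValueError("vertical alignment needs at least 2 slices")
    centers = []
    for ds in stack.slices:
        idx = edge_spots(ds, mode="vertical")
        centers.append(ds.coords[idx, :2].mean(axis=0))
    ref = centers[0]
    z = stack_z_coordinates(
        len(stack.slices), stack.thickness, stack.lam, stack.separations
    ) * stack.z_unit_scale
    parts = []
    for i, ds in enumerate(stack.slices):
        xy = ds.coords[:, :2].copy()
        if i > 0:
            xy -= centers[i] - ref
        parts.append(np.column_stack([xy, np.full(len(xy), z[i])]))
    stack.aligned_coords = np.vstack(parts)
    log.info(
        "align_vertical: %d slices, z = %s", len(stack.slices), np.round(z, 3)
    )
    return stack


def _merge_counts(left: SpotDataset, right: SpotDataset):
    """Concatenate two slices' counts over the shared gene set."""
    if left.gene_ids == right.gene_ids:
        genes = left.gene_ids
        lc, rc = left.counts, right.counts
    else:
        shared = [g for g in left.gene_ids if g in set(right.gene_ids)]
        if not shared:
            raise ValueError("slices share no genes")
        li = [left.gene_ids.index(g) for g in shared]
        ri = [right.gene_ids.index(g) for g in shared]
        lc = left.counts[:, li]
        rc = right.counts[:, ri]
        genes = shared
    if sparse.issparse(lc) or sparse.issparse(rc):
        merged = sparse.vstack([sparse.csr_matrix(lc), sparse.csr_matrix(rc)])
    else:
        merged = np.vstack([np.asarray(lc), np.asarray(rc)])
    return merged, genes


def align_horizontal(
    left: SpotDataset, right: SpotDataset, tol: Optional[float] = None
) -> SpotDataset:
    """Abut the right slice against the left and merge into one dataset.

    The y-bias is the difference of mean y between the left slice's
    rightmost spots and the right slice's leftmost spots; the x-shift is
    max(x_left) - min(x_right).  The left slice stays fixed.  The merged
    dataset can itself be re-aligned against further slices.
    """
    ridx = edge_spots(left, mode="horizontal", side="right", tol=tol)
    lidx = edge_spots(right, mode="horizontal", side="left", tol=tol)
    y1 = left.coords[ridx, 1].mean()
    y2 = right.coords[lidx, 1].mean()
    dx = left.coords[:, 0].max() - right.coords[:, 0].min()
    dy = y1 - y2
    shifted = right.coords[:, :2] + np.array([dx, dy])

    counts, genes = _merge_counts(left, right)
    left_ids = list(left.spot_ids)
    right_ids = list(right.spot_ids)
    if set(left_ids) & set(right_ids):
        left_ids = [f"{s}_{left.slice_id}" for s in left_ids]
        right_ids = [f"{s}_{right.slice_id}" for s in right_ids]
    merged = SpotDataset(
        counts=counts,
        gene_ids=genes,
        spot_ids=left_ids + right_ids,
        coords=np.vstack([left.coords[:, :2], shifted]),
        slice_id=f"{left.slice_id}+{right.slice_id}",
        labels=(
            list(left.labels) + list(right.labels)
            if left.labels is not None and right.labels is not None
            else None
        ),
    )
    log.info(
        "align_horizontal: shift (%.4g, %.4g), merged n=%d", -dx, -dy, merged.n_spots
    )
    return merged


def cross_slice_graph(
    stack: SliceStack, radius: float | str = "auto", force: bool = True
) -> SpatialGraph:
    """Radius graph on the aligned 3D coordinates of a vertical stack.

    The radius is not constrained to the in-plane (d, 2d) interval: slices
    sit much closer in z than spots do in x/y, so useful cross-slice radii
    lie below the grid pitch.  Warns when the inter-slice z-gap meets or
    exceeds the radius, since the graph then contains no cross-slice edges
    and the stack decouples into independent slices.
    """
    if stack.aligned_coords is None:
        if len(stack.slices) == 1:
            ds = stack.slices[0]
            stack.aligned_coords = np.column_stack(
                [ds.coords[:, :2], np.zeros(ds.n_spots)]
            )
        else:
            raise ValueError("align the stack before building the cross-slice graph")
    coords = stack.aligned_coords
    g = build_graph(coords, radius=radius, spacing=None, force=force)
    zs = np.unique(coords[:, 2])
    if len(zs) > 1:
        min_gap = np.diff(np.sort(zs)).min()
        if min_gap >= g.radius:
            warnings.warn(
                f"inter-slice gap {min_gap:.4g} >= radius {g.radius:.4g}: "
                "no cross-slice edges"
            )
    return g
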