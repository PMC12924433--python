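"""Spatial neighborhood graph: a radius graph on spot coordinates.

Spots i and j are connected iff their Euclidean distance is strictly less
than the radius r; every spot also carries a self-loop.  The published rule
requires r in the open interval (d, 2d), d being the spacing between
adjacent spots, with r = 1.5 d as the automatic choice.  The same
construction serves 2D single-slice coordinates and 3D aligned stacks.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

log = logging.getLogger("spotfuse")

__all__ = ["SpatialGraph", "build_graph"]


@dataclasses.dataclass
class SpatialGraph:
    """Binary symmetric adjacency with self-loops, kept as an edge list.

    ``edge_src``/``edge_dst`` enumerate all directed pairs (j, i) with
    A_ij = 1, self-loops included, so that messages flow j -> i over
    ``dst``'s neighborhood.  A dense matrix is materialized on demand.
    """

    n: int
    radius: float
    edge_src: np.ndarray  # j indices
    edge_dst: np.ndarray  # i indices

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    def adjacency(self) -> sparse.csr_matrix:
        a = sparse.coo_matrix(
            (np.ones(self.n_edges), (self.edge_dst, self.edge_src)),
            shape=(self.n, self.n),
        )
        return a.tocsr()

    def dense(self) -> np.ndarray:
        if self.n > 5000:
            raise ValueError("dense adjacency is limited to n <= 5000")
        return np.asarray(self.adjacency().todense())

    def degrees(self) -> np.ndarray:
        return np.bincount(self.edge_dst, minlength=self.n)

    def write_edge_list(self, path, coords: np.ndarray | None = None) -> None:
        """TSV export of undirected edges (i, j[, distance]); no self-loops."""
        with open(path, "w") as fh:
            fh.write("i\tj\tdistance\n" if coords is not None else "i\tj\n")
            for j, i in zip(self.edge_src, self.edge_dst):
                if j >= i:
                    continue
                if coords is not None:
                    d = float(np.linalg.norm(coords[i] - coords[j]))
                    fh.write(f"{i}\t{j}\t{d:.17g}\n")
                else:
                    fh.write(f"{i}\t{j}\n")


def build_graph(
    coords: np.ndarray,
    radius: float | str = "auto",
    spacing: float | None = None,
    force: bool = False,
) -> SpatialGraph:
    """Build the radius graph on n x k coordinates (k in {2, 3}).

    ``radius="auto"`` uses 1.5 * spacing (the midpoint of the valid (d, 2d)
    interval).  A numeric radius outside (d, 2d) raises unless ``force`` is
    set — the rule exists because a radius below d isolates every spot and
    one above 2d merges unrelated neighborhoods.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] not in (2, 3):
        raise ValueError("coords must be n x 2 or n x 3")
    n = coords.shape[0]
    if n == 0:
        raise ValueError("cannot build a graph on zero spots")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")

    if spacing is None and n >= 2:
        from .data import estimate_spot_spacing

        spacing = estimate_spot_spacing(coords)
    if radius == "auto":
        if spacing is None:
            raise ValueError("auto radius needs a spot spacing")
        r = 1.5 * spacing
    else:
        r = float(radius)
        if spacing is not None and not (spacing < r < 2 * spacing) and not force:
            raise ValueError(
                f"radius {r} outside the valid interval ({spacing}, {2 * spacing}); "
                "pass force=True to override"
            )
    if r <= 0:
        raise ValueError("radius must be positive")

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r, output_type="ndarray")  # strict: dist < r
    if pairs.size:
        # query_pairs uses dist <= r; drop exact-distance ties to keep "< r" strict
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]
    loops = np.arange(n)
    src = np.concatenate([pairs[:, 0], pairs[:, 1], loops]) if pairs.size else loops
    dst = np.concatenate([pairs[:, 1], pairs[:, 0], loops]) if pairs.size else loops
    order = np.lexsort((src, dst))
    g = SpatialGraph(n=n, radius=r, edge_src=src[order], edge_dst=dst[order])
    log.info("build_graph: n=%d, r=%.4g, %d directed edges", n, r, g.n_edges)
    return g
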