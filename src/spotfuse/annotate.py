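"""Transfer of pathologist polygon annotations onto spots.

Region annotations drawn with labelme-style tools are simple polygons in
image-pixel coordinates.  Spot membership uses the ray-casting crossing
number: a ray from the spot in the +x direction crosses the polygon
boundary an odd number of times iff the spot is inside.  Edges follow the
half-open rule (an edge's lower-y vertex is included, the upper excluded)
so rays through vertices are never double counted and a point on a shared
edge of two adjacent polygons belongs to exactly one of them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("spotfuse")

__all__ = [
    "AnnotationSet",
    "read_labelme_json",
    "point_in_polygon",
    "spots_to_labels",
]


@dataclasses.dataclass
class AnnotationSet:
    """Ordered (region_name, vertices) polygons in image pixels."""

    polygons: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        cleaned = []
        for name, verts in self.polygons:
            verts = np.asarray(verts, dtype=float)
            # drop an explicit closing vertex; closure is implicit
            if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
                verts = verts[:-1]
            if len(verts) < 3:
                raise ValueError(f"polygon '{name}' has fewer than 3 vertices")
            cleaned.append((name, verts))
        self.polygons = cleaned

    @property
    def region_names(self) -> list[str]:
        return [name for name, _ in self.polygons]


def read_labelme_json(path) -> AnnotationSet:
    """Read a labelme-style JSON file ({"shapes": [{"label", "points"}, ...]})."""
    with open(path) as fh:
        doc = json.load(fh)
    polys = [
        (shape["label"], np.asarray(shape["points"], dtype=float))
        for shape in doc.get("shapes", [])
        if shape.get("shape_type", "polygon") == "polygon"
    ]
    if not polys:
        raise ValueError(f"{path}: no polygon shapes found")
    return AnnotationSet(polys)


def _polygon_area2(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def point_in_polygon(point, polygon, ray: str = "+x") -> bool:
    """Crossing-number membership test for a simple polygon.

    Casts a ray from ``point`` (in the +x direction by default, +y as an
    alternative) and counts boundary crossings with the half-open edge
    rule; an odd count means inside.  Degenerate (zero-area) polygons are
    always outside.
    """
    verts = np.asarray(polygon, dtype=float)
    if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if len(verts) < 3 or _polygon_area2(verts) == 0.0:
        warnings.warn("degenerate polygon: treating all points as outside")
        return False
    px, py = float(point[0]), float(point[1])
    if ray == "+y":  # reuse the +x logic in swapped coordinates
        verts = verts[:, ::-1]
        px, py = py, px
    elif ray != "+x":
        raise ValueError("ray must be '+x' or '+y'")
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    crossings = 0
    for x0, y0, x1, y1 in zip(x, y, xn, yn):
        # half-open in y: lower vertex included, upper excluded
        if (y0 <= py < y1) or (y1 <= py < y0):
            x_at = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            if x_at > px:
                crossings += 1
    return crossings % 2 == 1


def spots_to_labels(
    coords: np.ndarray, annotations: AnnotationSet
) -> tuple[np.ndarray, np.ndarray]:
    """Label each spot with the first containing region, in annotation order.

    Returns ``(labels, unassigned)``: labels is an object array of region
    names (None where unassigned), unassigned a boolean mask.  Overlaps are
    resolved by annotation order and logged.
    """
    if not annotations.polygons:
        raise ValueError("empty annotation set")
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    labels = np.full(n, None, dtype=object)
    n_overlap = 0
    for i in range(n):
        hits = [
            name
            for name, verts in annotations.polygons
            if point_in_polygon(coords[i], verts)
        ]
        if hits:
            labels[i] = hits[0]
            if len(hits) > 1:
                n_overlap += 1
    if n_overlap:
        log.info(
            "spots_to_labels: %d spots in overlapping regions (first wins)",
            n_overlap,
        )
    unassigned = np.array([l is None for l in labels])
    return labels, unassigned


def write_spot_labels(path, spot_ids: Sequence[str], labels: np.ndarray) -> None:
    pd.DataFrame(
        {"label": ["" if l is None else l for l in labels]},
        index=pd.Index(spot_ids, name="spot_id"),
    ).to_csv(path)
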