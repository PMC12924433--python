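"""Core data model and I/O for spatial-transcriptomics slices.

A slice is represented by :class:`SpotDataset`: a spot-by-gene count matrix,
per-spot spatial coordinates (image-pixel convention: origin top-left,
x rightward, y downward, 0-based), an optional histology image reference and
optional ground-truth labels.  Readers accept 10x Visium-style MTX
directories and plain dense CSV/TSV tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from scipy.spatial import cKDTree

log = logging.getLogger("spotfuse")

__all__ = [
    "SpotDataset",
    "RunConfig",
    "FormatError",
    "ConsistencyError",
    "estimate_spot_spacing",
    "read_visium_dir",
    "read_dense_table",
    "write_results",
]


class FormatError(ValueError):
    """A required file or component of an on-disk format is missing/invalid."""


class ConsistencyError(ValueError):
    """Row-aligned inputs disagree (ids, lengths, shapes)."""


def estimate_spot_spacing(coords: np.ndarray) -> float:
    """Median over spots of the nearest-neighbor Euclidean distance.

    This is the spacing ``d`` between adjacent spots used to pick the
    neighborhood radius; on a regular grid it equals the grid pitch.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("spot spacing needs at least 2 spots")
    k = min(coords.shape[0], 8)
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=k)
    # coincident spots (e.g. merged slices sharing a cut-surface column)
    # contribute zero distances; the spacing is the first positive gap
    pos = np.where(dist[:, 1:] > 0, dist[:, 1:], np.inf).min(axis=1)
    pos = pos[np.isfinite(pos)]
    if pos.size == 0:
        raise ValueError("all spots are coincident; cannot estimate spacing")
    return float(np.median(pos))


@dataclasses.dataclass
class SpotDataset:
    """One tissue slice: counts, coordinates and optional side information."""

    counts: np.ndarray | sparse.spmatrix  # n spots x g genes, non-negative
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray  # n x 2 (or n x 3 after 3D alignment)
    slice_id: str = "slice0"
    spot_spacing: Optional[float] = None
    image_path: Optional[Path] = None
    labels: Optional[list] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.n_spots
        if len(self.spot_ids) != n or self.coords.shape[0] != n:
            raise ConsistencyError(
                f"row-aligned fields disagree: counts {n} rows, "
                f"{len(self.spot_ids)} spot ids, coords {self.coords.shape[0]} rows"
            )
        if len(self.gene_ids) != self.n_genes:
            raise ConsistencyError("gene_ids length does not match counts columns")
        if self.labels is not None and len(self.labels) != n:
            raise ConsistencyError("labels length does not match spot count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        mn = self.counts.min() if sparse.issparse(self.counts) else np.min(self.counts)
        if n and self.n_genes and mn < 0:
            raise ValueError("counts must be non-negative")
        if self.spot_spacing is None and n >= 2:
            self.spot_spacing = estimate_spot_spacing(self.coords[:, :2])
        if self.spot_spacing is not None and self.spot_spacing <= 0:
            raise ValueError("spot_spacing must be positive")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def counts_dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)


@dataclasses.dataclass
class RunConfig:
    """Hyperparameters of the full pipeline with the published defaults.

    ``radius`` may be the string ``"auto"`` (then 1.5 * spot spacing) or a
    number, which must lie strictly between d and 2d at graph-build time.
    ``beta`` weighs the contrastive term against reconstruction.
    """

    n_hvg: int = 3000
    radius: float | str = "auto"
    crop_size: int = 40  # h = w, pixels
    patch_size: int = 8
    n_image_pcs: int = 3000
    f1_latent: int = 100  # expression-branch latent width
    f2_latent: int = 100  # histology-branch latent width
    f_joint: int = 200  # concatenated joint input width
    f_embed: int = 30  # final embedding width
    hidden: int = 512  # first-layer width of each modality encoder
    vit_heads: int = 12
    vit_layers: int = 6
    beta: float = 0.04
    lr: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 1200
    seed: int = 0
    clusterer: str = "gmm"  # {"gmm", "louvain"}
    n_clusters: Optional[int] = None
    resolution: float = 1.0
    refine: bool = False
    refine_k: int = 50
    log_before_norm: bool = False  # alternative preprocessing step order
    scale_clip: Optional[float] = None

    def __post_init__(self) -> None:
        if self.f_joint != self.f1_latent + self.f2_latent:
            raise ValueError("f_joint must equal f1_latent + f2_latent")
        for name in ("n_hvg", "crop_size", "patch_size", "n_image_pcs", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta < 0 or self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer settings")
        if self.clusterer not in ("gmm", "louvain"):
            raise ValueError("clusterer must be 'gmm' or 'louvain'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _find_one(path: Path, patterns: Sequence[str], what: str) -> Path:
    for pat in patterns:
        hits = sorted(path.glob(pat))
        if hits:
            return hits[0]
    raise FormatError(f"{path}: missing {what} (looked for {', '.join(patterns)})")


def read_visium_dir(path: str | Path, slice_id: Optional[str] = None) -> SpotDataset:
    """Read a 10x Visium-style directory (MTX matrix + positions table).

    Expected contents: ``matrix.mtx[.gz]`` with ``barcodes.tsv`` and
    ``features.tsv``/``genes.tsv``, plus a spot-position table
    (``tissue_positions*.csv`` or ``positions.csv``) whose pixel columns give
    the full-resolution spot centers.  Matrix orientation follows the 10x
    convention (genes x barcodes).  An optional ``scalefactors*.json`` may
    carry ``spot_spacing``; otherwise spacing is estimated as the median
    nearest-neighbor distance.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not a directory")
    mtx = _find_one(path, ["matrix.mtx", "matrix.mtx.gz", "*.mtx"], "MTX matrix")
    bc = _find_one(path, ["barcodes.tsv", "barcodes.tsv.gz"], "barcodes table")
    feat = _find_one(
        path, ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"],
        "features/genes table",
    )
    pos = _find_one(
        path,
        ["tissue_positions_list.csv", "tissue_positions.csv", "positions.csv"],
        "spot positions table",
    )

    mat = sparse.csr_matrix(mmread(str(mtx)).T)  # -> spots x genes
    barcodes = pd.read_csv(bc, sep="\t", header=None)[0].astype(str).tolist()
    genes_df = pd.read_csv(feat, sep="\t", header=None)
    gene_col = 1 if genes_df.shape[1] > 1 else 0
    gene_ids = genes_df[gene_col].astype(str).tolist()
    if mat.shape[0] != len(barcodes) or mat.shape[1] != len(gene_ids):
        raise ConsistencyError(
            f"matrix shape {mat.shape} does not match "
            f"{len(barcodes)} barcodes x {len(gene_ids)} genes"
        )

    first = pd.read_csv(pos, header=None, nrows=1)
    has_header = str(first.iloc[0, 0]).strip().lower() in ("barcode", "spot_id")
    pos_df = pd.read_csv(pos, header=0 if has_header else None)
    if not has_header:
        pos_df.columns = _POSITION_COLUMNS[: pos_df.shape[1]]
    pos_df = pos_df.set_index(pos_df.columns[0])
    pos_df.index = pos_df.index.astype(str)
    missing = [b for b in barcodes if b not in pos_df.index]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} barcodes lack positions (e.g. {missing[:3]})"
        )
    pos_df = pos_df.loc[barcodes]
    if "in_tissue" in pos_df.columns:
        keep = pos_df["in_tissue"].astype(int).to_numpy() == 1
    else:
        keep = np.ones(len(barcodes), dtype=bool)
    # x = pixel column, y = pixel row (image convention)
    coords = np.column_stack(
        [
            pos_df["pxl_col_in_fullres"].to_numpy(float),
            pos_df["pxl_row_in_fullres"].to_numpy(float),
        ]
    )[keep]
    barcodes = [b for b, k in zip(barcodes, keep) if k]
    mat = mat[keep]

    spacing = None
    image_path = None
    sf = sorted(path.glob("scalefactors*.json"))
    if sf:
        with open(sf[0]) as fh:
            meta = json.load(fh)
        spacing = meta.get("spot_spacing")
    for name in ("image.png", "image.tif", "image.tiff", "image.jpg"):
        if (path / name).exists():
            image_path = path / name
            break

    labels = None
    lab = path / "labels.csv"
    if lab.exists():
        lab_df = pd.read_csv(lab, index_col=0)
        lab_df.index = lab_df.index.astype(str)
        labels = lab_df.reindex(barcodes).iloc[:, 0].tolist()

    ds = SpotDataset(
        counts=mat,
        gene_ids=gene_ids,
        spot_ids=barcodes,
        coords=coords,
        slice_id=slice_id or path.name,
        spot_spacing=spacing,
        image_path=image_path,
        labels=labels,
    )
    log.info(
        "read_visium_dir %s: %d spots x %d genes, d=%.3g",
        path, ds.n_spots, ds.n_genes, ds.spot_spacing or float("nan"),
    )
    return ds


def read_dense_table(
    path: str | Path,
    coords_path: str | Path,
    orientation: str = "auto",
    slice_id: Optional[str] = None,
) -> SpotDataset:
    """Read a dense expression table plus a coordinate table.

    ``orientation`` is ``"spots"`` (rows are spots), ``"genes"`` (rows are
    genes) or ``"auto"``, which picks whichever axis shares more ids with the
    coordinate table.  Spot ids present in only one table are dropped; an
    empty intersection is an error.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    expr = pd.read_csv(path, sep=sep, index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    csep = "\t" if str(coords_path).endswith((".tsv", ".txt")) else ","
    cdf = pd.read_csv(coords_path, sep=csep, index_col=0)
    cdf.index = cdf.index.astype(str)

    if orientation == "auto":
        n_row = len(set(expr.index) & set(cdf.index))
        n_col = len(set(expr.columns) & set(cdf.index))
        orientation = "genes" if n_col > n_row else "spots"
    if orientation == "genes":
        expr = expr.T
    elif orientation != "spots":
        raise ValueError("orientation must be 'auto', 'spots' or 'genes'")

    shared = [s for s in expr.index if s in cdf.index]
    if not shared:
        raise ConsistencyError(
            "no spot ids shared between expression and coordinate tables"
        )
    expr = expr.loc[shared]
    cdf = cdf.loc[shared]
    xy_cols = [c for c in cdf.columns if c.lower() in ("x", "y")]
    coords = (
        cdf[sorted(xy_cols, key=str.lower)].to_numpy(float)
        if len(xy_cols) == 2
        else cdf.iloc[:, :2].to_numpy(float)
    )
    return SpotDataset(
        counts=expr.to_numpy(float),
        gene_ids=expr.columns.tolist(),
        spot_ids=shared,
        coords=coords,
        slice_id=slice_id or Path(path).stem,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_results(
    dataset: SpotDataset,
    embedding: np.ndarray,
    labels: Sequence,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
) -> Path:
    """Write embedding, labels, aligned coordinates and configuration.

    Produces ``embedding.csv`` (spot_id + one column per latent dim),
    ``labels.csv``, ``coords.csv`` (x, y and z when the dataset carries 3D
    coordinates) and ``config.json``.  The label column round-trips exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    embedding = np.asarray(embedding, dtype=float)
    n = dataset.n_spots
    if embedding.shape[0] != n:
        raise ConsistencyError(
            f"embedding has {embedding.shape[0]} rows for {n} spots"
        )
    if len(labels) != n:
        raise ConsistencyError(f"labels has {len(labels)} entries for {n} spots")

    emb = pd.DataFrame(
        embedding,
        index=pd.Index(dataset.spot_ids, name="spot_id"),
        columns=[f"dim{i}" for i in range(embedding.shape[1])],
    )
    emb.to_csv(out_dir / "embedding.csv", float_format="%.17g")
    pd.DataFrame(
        {"label": list(labels)}, index=pd.Index(dataset.spot_ids, name="spot_id")
    ).to_csv(out_dir / "labels.csv")
    cols = ["x", "y", "z"][: dataset.coords.shape[1]]
    pd.DataFrame(
        dataset.coords, index=pd.Index(dataset.spot_ids, name="spot_id"), columns=cols
    ).to_csv(out_dir / "coords.csv", float_format="%.17g")
    if config is not None:
        with open(out_dir / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, default=str)
    log.info("write_results -> %s (n=%d, f'=%d)", out_dir, n, embedding.shape[1])
    return out_dir


def write_visium_dir(dataset: SpotDataset, out_dir: str | Path) -> Path:
    """Write a dataset in the MTX directory layout that read_visium_dir reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = dataset.counts
    if not sparse.issparse(mat):
        mat = sparse.csr_matrix(mat)
    mmwrite(str(out_dir / "matrix.mtx"), mat.T.tocoo())  # genes x barcodes
    with open(out_dir / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(dataset.spot_ids) + "\n")
    with open(out_dir / "features.tsv", "w") as fh:
        for g in dataset.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    pos = pd.DataFrame(
        {
            "barcode": dataset.spot_ids,
            "in_tissue": 1,
            "array_row": 0,
            "array_col": 0,
            "pxl_row_in_fullres": dataset.coords[:, 1],
            "pxl_col_in_fullres": dataset.coords[:, 0],
        }
    )
    pos.to_csv(out_dir / "tissue_positions.csv", index=False)
    if dataset.spot_spacing is not None:
        with open(out_dir / "scalefactors.json", "w") as fh:
            json.dump({"spot_spacing": dataset.spot_spacing}, fh)
    if dataset.labels is not None:
        pd.DataFrame(
            {"label": dataset.labels},
            index=pd.Index(dataset.spot_ids, name="barcode"),
        ).to_csv(out_dir / "labels.csv")
    return out_dir
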