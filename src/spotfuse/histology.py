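"""Histology feature extraction: spot crops, patch sequences, a vision
transformer encoder and joint PCA reduction.

Each spot's h x w x 3 neighborhood of the H&E image is split into
N = h*w/p^2 patches, linearly embedded to 768-dim tokens, passed through a
stack of pre-norm multi-head self-attention blocks, projected token-wise to
1000 dims and flattened, giving an n x (N*1000) matrix that PCA reduces to
the per-spot feature matrix I.  Weights are seeded-random by default; a
checkpoint of pretrained tensors (same schema as ``HViT.state_dict``) can
be supplied instead.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
from PIL import Image
from sklearn.decomposition import PCA

log = logging.getLogger("spotfuse")

__all__ = [
    "SpotImageBatch",
    "HistologyFeatureMatrix",
    "crop_spots",
    "patchify",
    "unpatchify",
    "HViT",
    "hvit_encode",
    "pca_reduce",
]

TOKEN_DIM = 768
HEAD_DIM_TOTAL = 768
OUT_DIM = 1000
MLP_RATIO = 4


@dataclasses.dataclass
class SpotImageBatch:
    """n crops of shape h x w x 3 with values normalized to [0, 1]."""

    crops: np.ndarray  # (n, h, w, 3)

    def __post_init__(self) -> None:
        c = self.crops
        if c.ndim != 4 or c.shape[3] != 3 or c.shape[1] != c.shape[2]:
            raise ValueError("crops must be (n, h, h, 3)")
        if c.size and (c.min() < 0 or c.max() > 1):
            raise ValueError("crop values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.crops.shape[0]

    @property
    def h(self) -> int:
        return self.crops.shape[1]


@dataclasses.dataclass
class HistologyFeatureMatrix:
    """Per-spot image features I (n x f2) plus the fitted PCA projection."""

    I: np.ndarray
    components: np.ndarray  # (f2, m)
    mean: np.ndarray  # (m,)
    explained_variance: np.ndarray


# ---------------------------------------------------------------------------
# Cropping and patching
# ---------------------------------------------------------------------------

def _load_image(image) -> np.ndarray:
    if isinstance(image, np.ndarray):
        arr = image
    else:
        arr = np.asarray(Image.open(image).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def crop_spots(image, coords: np.ndarray, h: int = 40) -> SpotImageBatch:
    """One h x h x 3 crop centered on each spot (image convention: x = column,
    y = row).  Crops reaching past the border are padded by edge replication.
    """
    img = _load_image(image)
    coords = np.asarray(coords, dtype=float)
    H, W = img.shape[:2]
    bad = [
        i
        for i, (x, y) in enumerate(coords[:, :2])
        if x < -h or x > W + h or y < -h or y > H + h
    ]
    if bad:
        raise ValueError(f"spot centers far outside image bounds: {bad[:10]}")
    padded = np.pad(img, ((h, h), (h, h), (0, 0)), mode="edge")
    half = h // 2
    crops = np.empty((len(coords), h, h, 3), dtype=np.float64)
    for i, (x, y) in enumerate(coords[:, :2]):
        r = int(round(y)) + h - half
        c = int(round(x)) + h - half
        crops[i] = padded[r : r + h, c : c + h]
    return SpotImageBatch(np.clip(crops, 0.0, 1.0))


def patchify(crop: np.ndarray, p: int) -> np.ndarray:
    """Split an h x w x 3 crop into the N x (p*p*3) patch sequence.

    Patches are enumerated row-major over the crop; each patch is flattened
    channel-last.  Requires h and w divisible by p.
    """
    h, w = crop.shape[:2]
    if h % p or w % p:
        raise ValueError(
            f"crop side {h}x{w} not divisible by patch size {p}; resize the crop"
        )
    seq = (
        crop.reshape(h // p, p, w // p, p, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape((h // p) * (w // p), p * p * 3)
    )
    return seq


def unpatchify(seq: np.ndarray, h: int, p: int) -> np.ndarray:
    """Inverse of :func:`patchify` for square crops."""
    g = h // p
    return (
        seq.reshape(g, g, p, p, 3).transpose(0, 2, 1, 3, 4).reshape(h, h, 3)
    )


# ---------------------------------------------------------------------------
# Vision transformer
# ---------------------------------------------------------------------------

def _layer_norm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return gamma * (x - mu) / (sd + 1e-6) + beta


_SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))


def _gelu(x: np.ndarray) -> np.ndarray:
    # python-float constants keep float32 inputs in float32 (no silent upcast)
    return 0.5 * x * (1.0 + np.tanh(_SQRT_2_OVER_PI * x * (1.0 + 0.044715 * x * x)))


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.exp(x - x.max(axis=axis, keepdims=True))
    return z / z.sum(axis=axis, keepdims=True)


class HViT:
    """Pre-norm vision transformer over spot-image patch sequences.

    ``heads`` attention heads and ``layers`` MSA+MLP blocks over 768-dim
    tokens (defaults 12 and 6), learned positional embeddings, and a final
    per-token linear head to 1000 dims.  Forward-only: the encoder is used
    as a fixed feature extractor, either with seeded-random weights or with
    weights loaded from a checkpoint.
    """

    def __init__(
        self,
        patch_dim: int,
        n_patches: int,
        heads: int = 12,
        layers: int = 6,
        seed: int = 0,
        use_positional: bool = True,
    ):
        if TOKEN_DIM % heads:
            raise ValueError(f"heads must divide the token width {TOKEN_DIM}")
        self.heads, self.layers = heads, layers
        self.n_patches = n_patches
        self.use_positional = use_positional
        rng = np.random.default_rng(seed)
        sd = 0.02

        def init(*shape):
            return rng.normal(0.0, sd, size=shape)

        self.params: dict[str, np.ndarray] = {
            "patch_embed.W": init(patch_dim, TOKEN_DIM),
            "pos_embed": init(n_patches, TOKEN_DIM),
            "head.W": init(TOKEN_DIM, OUT_DIM),
            "head.b": np.zeros(OUT_DIM),
        }
        for l in range(layers):
            p = self.params
            p[f"block{l}.ln1.g"] = np.ones(TOKEN_DIM)
            p[f"block{l}.ln1.b"] = np.zeros(TOKEN_DIM)
            p[f"block{l}.Wq"] = init(TOKEN_DIM, TOKEN_DIM)
            p[f"block{l}.Wk"] = init(TOKEN_DIM, TOKEN_DIM)
            p[f"block{l}.Wv"] = init(TOKEN_DIM, TOKEN_DIM)
            p[f"block{l}.Wt"] = init(TOKEN_DIM, TOKEN_DIM)
            p[f"block{l}.ln2.g"] = np.ones(TOKEN_DIM)
            p[f"block{l}.ln2.b"] = np.zeros(TOKEN_DIM)
            p[f"block{l}.mlp.W1"] = init(TOKEN_DIM, MLP_RATIO * TOKEN_DIM)
            p[f"block{l}.mlp.b1"] = np.zeros(MLP_RATIO * TOKEN_DIM)
            p[f"block{l}.mlp.W2"] = init(MLP_RATIO * TOKEN_DIM, TOKEN_DIM)
            p[f"block{l}.mlp.b2"] = np.zeros(TOKEN_DIM)

    def state_dict(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        bad = []
        for key, val in self.params.items():
            if key not in state:
                bad.append(f"{key}: missing")
            elif np.asarray(state[key]).shape != val.shape:
                bad.append(
                    f"{key}: shape {np.asarray(state[key]).shape} != {val.shape}"
                )
        if bad:
            raise ValueError("checkpoint mismatch: " + "; ".join(bad))
        for key in self.params:
            self.params[key] = np.asarray(state[key], dtype=np.float64)

    def _attention(
        self, tokens: np.ndarray, l: int, f32
    ) -> tuple[np.ndarray, np.ndarray]:
        n, N, _ = tokens.shape
        dk = TOKEN_DIM // self.heads
        flat = tokens.reshape(n * N, TOKEN_DIM)
        q = (flat @ f32[f"block{l}.Wq"]).reshape(n, N, self.heads, dk)
        k = (flat @ f32[f"block{l}.Wk"]).reshape(n, N, self.heads, dk)
        v = (flat @ f32[f"block{l}.Wv"]).reshape(n, N, self.heads, dk)
        scores = np.einsum("nihd,njhd->nhij", q, k) / np.sqrt(dk)
        amap = _softmax(scores, axis=-1)  # (n, heads, N, N), rows sum to 1
        mixed = np.einsum("nhij,njhd->nihd", amap, v).reshape(n * N, TOKEN_DIM)
        return (mixed @ f32[f"block{l}.Wt"]).reshape(n, N, TOKEN_DIM), amap

    def _forward_tokens(self, seqs: np.ndarray, f32: dict, attns: list | None):
        n, N = seqs.shape[0], seqs.shape[1]
        tokens = seqs.astype(np.float32) @ f32["patch_embed.W"]
        if self.use_positional:
            tokens = tokens + f32["pos_embed"]
        for l in range(self.layers):
            normed = _layer_norm(tokens, f32[f"block{l}.ln1.g"], f32[f"block{l}.ln1.b"])
            mixed, amap = self._attention(normed, l, f32)
            if attns is not None:
                attns.append(amap)
            tokens = tokens + mixed
            normed = _layer_norm(tokens, f32[f"block{l}.ln2.g"], f32[f"block{l}.ln2.b"])
            flat = normed.reshape(n * N, TOKEN_DIM)
            hidden = _gelu(flat @ f32[f"block{l}.mlp.W1"] + f32[f"block{l}.mlp.b1"])
            tokens = tokens + (hidden @ f32[f"block{l}.mlp.W2"]
                               + f32[f"block{l}.mlp.b2"]).reshape(n, N, TOKEN_DIM)
        out = tokens.reshape(n * N, TOKEN_DIM) @ f32["head.W"] + f32["head.b"]
        return out.reshape(n, N * OUT_DIM)

    def forward(
        self,
        batch: SpotImageBatch,
        p: int,
        return_attention: bool = False,
        chunk: int = 32,
    ):
        """Encode crops to the flattened n x (N*1000) feature matrix.

        The forward pass runs in float32 (the encoder is a fixed feature
        extractor, so single precision is ample), with matrix products
        reshaped to 2D for BLAS and spots processed in chunks to bound the
        size of intermediate buffers.
        """
        if batch.n == 0:
            raise ValueError("empty crop batch")
        seqs = np.stack([patchify(c, p) for c in batch.crops])  # (n, N, p*p*3)
        if seqs.shape[1] != self.n_patches:
            raise ValueError(
                f"crop yields {seqs.shape[1]} patches, model expects {self.n_patches}"
            )
        f32 = {k: np.asarray(v, dtype=np.float32) for k, v in self.params.items()}
        attns: list | None = [] if return_attention else None
        parts = [
            self._forward_tokens(seqs[i : i + chunk], f32, attns)
            for i in range(0, batch.n, chunk)
        ]
        flat_out = np.vstack(parts).astype(np.float64)
        if return_attention:
            # regroup per-layer attention maps across chunks
            L = self.layers
            grouped = [
                np.concatenate(attns[l::L], axis=0) for l in range(L)
            ]
            return flat_out, grouped
        return flat_out


def hvit_encode(
    batch: SpotImageBatch,
    patch_size: int = 8,
    heads: int = 12,
    layers: int = 6,
    seed: int = 0,
    checkpoint: Optional[dict[str, np.ndarray]] = None,
) -> np.ndarray:
    """Convenience wrapper: build a (seeded or checkpointed) HViT and encode."""
    h = batch.h
    if h % patch_size:
        raise ValueError(
            f"crop side {h} not divisible by patch size {patch_size}"
        )
    N = (h // patch_size) ** 2
    model = HViT(patch_size**2 * 3, N, heads=heads, layers=layers, seed=seed)
    if checkpoint is not None:
        model.load_state_dict(checkpoint)
    feats = model.forward(batch, patch_size)
    log.info("hvit_encode: %d crops -> %s features", batch.n, feats.shape)
    return feats


def pca_reduce(features: np.ndarray, k: int = 3000) -> HistologyFeatureMatrix:
    """Mean-centered PCA keeping min(k, n-1, m) components.

    Component signs are fixed so each component's largest-magnitude loading
    is positive, making the projection deterministic.
    """
    features = np.asarray(features, dtype=np.float64)
    n, m = features.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    k = int(min(k, n - 1, m))
    pca = PCA(n_components=k, svd_solver="full" if min(n, m) < 2000 else "randomized",
              random_state=0)
    proj = pca.fit_transform(features)
    comps = pca.components_.copy()
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            proj[:, i] = -proj[:, i]
    return HistologyFeatureMatrix(
        I=proj,
        components=comps,
        mean=pca.mean_.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )
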