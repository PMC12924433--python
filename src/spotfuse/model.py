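"""Multi-modal graph attention auto-encoder with contrastive learning.

Two modality encoders (gene expression, histology features) and a joint
encoder are stacks of graph attention layers over the spatial neighborhood
graph.  Each layer computes edge scores

    e_ij = sigmoid(v_s' ELU(W h_i) + v_k' ELU(W h_j))

normalized by a softmax over each spot's neighborhood (self-loops included)
to attention coefficients alpha_ij, and aggregates

    h_i <- ELU(sum_j alpha_ij W h_j).

The decoder mirrors the encoder with tied weights and reused attention
coefficients, so it contributes no trainable parameters of its own.  The
reconstruction loss sums per-spot Euclidean errors for both the clean
(positive) stream and a corrupted (row-shuffled) negative stream.  A
deep-graph-infomax-style discriminator D(h, s) = sigmoid(h' B s) against the
sigmoid-of-mean graph summary s adds a binary cross-entropy contrastive
term, weighted by beta (default 0.04).  Training is full-batch Adam.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Optional

import numpy as np

from .autograd import Parameter, Tensor
from .data import RunConfig
from .graph import SpatialGraph

log = logging.getLogger("spotfuse")

__all__ = [
    "GclModel",
    "EmbeddingSet",
    "LossReport",
    "attention_coefficients",
    "neighborhood_softmax",
    "corrupt",
    "readout",
    "discriminate",
    "contrastive_loss",
    "reconstruction_loss",
    "train",
]

BCE_EPS = 1e-7


# ---------------------------------------------------------------------------
# Attention primitives
# ---------------------------------------------------------------------------

def neighborhood_softmax(e: Tensor, dst: np.ndarray, n: int) -> Tensor:
    """Softmax of edge scores within each destination's neighborhood.

    ``e`` has one row per directed edge (shape (E, 1)); rows with equal
    ``dst`` form one softmax group, so coefficients sum to 1 per spot.
    """
    # subtract the per-group max (a constant) for numerical stability
    m = np.full(n, -np.inf, dtype=e.data.dtype)
    np.maximum.at(m, dst, e.data[:, 0])
    z = (e - m[dst][:, None]).exp()
    denom = z.scatter_add(dst, n)
    return z / denom.gather_rows(dst)


def attention_coefficients(
    Z: Tensor,
    W: Tensor,
    v_s: Tensor,
    v_k: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    n: int,
) -> tuple[Tensor, Tensor]:
    """Per-edge attention alpha_ij and the projected features W h.

    Returns ``(alpha, Wh)`` where ``alpha`` has shape (E, 1) and rows with
    the same destination sum to 1, and ``Wh = Z W'`` is reused for the
    aggregation step.
    """
    Wh = Z @ W.T
    g = Wh.elu()
    es = g @ v_s  # (n, 1): source-role score of each spot
    ek = g @ v_k
    e = (es.gather_rows(dst) + ek.gather_rows(src)).sigmoid()
    return neighborhood_softmax(e, dst, n), Wh


class GATLayer:
    """One graph attention layer; holds W (out x in), v_s and v_k (out x 1)."""

    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float64
    ):
        lim = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Parameter(
            rng.uniform(-lim, lim, size=(out_dim, in_dim)).astype(dtype)
        )
        lim_v = np.sqrt(6.0 / (out_dim + 1))
        self.v_s = Parameter(rng.uniform(-lim_v, lim_v, size=(out_dim, 1)).astype(dtype))
        self.v_k = Parameter(rng.uniform(-lim_v, lim_v, size=(out_dim, 1)).astype(dtype))

    def parameters(self) -> list[Parameter]:
        return [self.W, self.v_s, self.v_k]

    def encode(self, Z: Tensor, graph: SpatialGraph) -> tuple[Tensor, Tensor]:
        alpha, Wh = attention_coefficients(
            Z, self.W, self.v_s, self.v_k, graph.edge_src, graph.edge_dst, graph.n
        )
        msg = alpha * Wh.gather_rows(graph.edge_src)
        return msg.scatter_add(graph.edge_dst, graph.n).elu(), alpha

    def decode(self, H: Tensor, alpha: Tensor, graph: SpatialGraph) -> Tensor:
        """Inverse pass with the tied weight (W') and the encoder's alpha."""
        msg = alpha * (H @ self.W).gather_rows(graph.edge_src)
        return msg.scatter_add(graph.edge_dst, graph.n).elu()


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EmbeddingSet:
    """Encoder outputs for one stream (tensors keep the autodiff tape)."""

    Z1: Tensor
    Z2: Optional[Tensor]
    H: Tensor
    alphas1: list[Tensor]
    alphas2: list[Tensor]
    alpha_joint: Tensor


@dataclasses.dataclass
class LossReport:
    beta: float
    l_gate_p: list[float] = dataclasses.field(default_factory=list)
    l_gate_n: list[float] = dataclasses.field(default_factory=list)
    l_gate: list[float] = dataclasses.field(default_factory=list)
    l_cl: list[float] = dataclasses.field(default_factory=list)
    l_total: list[float] = dataclasses.field(default_factory=list)
    d_pos_mean: list[float] = dataclasses.field(default_factory=list)
    d_neg_mean: list[float] = dataclasses.field(default_factory=list)


class GclModel:
    """Encoders + tied decoder + discriminator.

    ``f2 = None`` selects expression-only mode (platforms without histology):
    the image branch is dropped and the joint input width is the expression
    latent width alone.
    """

    def __init__(
        self,
        f1: int,
        f2: Optional[int],
        config: RunConfig,
        rng: Optional[np.random.Generator] = None,
        dtype=np.float64,
    ):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.dtype = np.dtype(dtype).type
        self.f1, self.f2 = f1, f2
        self.multimodal = f2 is not None
        h = config.hidden
        self.expr_layers = [
            GATLayer(f1, h, rng, dtype),
            GATLayer(h, config.f1_latent, rng, dtype),
        ]
        if self.multimodal:
            self.img_layers = [
                GATLayer(f2, h, rng, dtype),
                GATLayer(h, config.f2_latent, rng, dtype),
            ]
            f_joint = config.f1_latent + config.f2_latent
        else:
            self.img_layers = []
            f_joint = config.f1_latent
        self.f_joint = f_joint
        self.joint_layer = GATLayer(f_joint, config.f_embed, rng, dtype)
        lim = np.sqrt(6.0 / (2 * config.f_embed))
        self.B = Parameter(
            rng.uniform(-lim, lim, size=(config.f_embed, config.f_embed)).astype(dtype)
        )

    # -- parameter bookkeeping ----------------------------------------------
    def encoder_parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for layer in self.expr_layers + self.img_layers + [self.joint_layer]:
            ps.extend(layer.parameters())
        return ps

    def parameters(self) -> list[Parameter]:
        # the decoder is fully tied: it adds nothing beyond encoder + B
        return self.encoder_parameters() + [self.B]

    def parameter_count(self, include_decoder: bool = True) -> int:
        del include_decoder  # tied weights: the count is identical either way
        return sum(p.data.size for p in self.parameters())

    # -- forward passes ------------------------------------------------------
    def encode(self, X: Tensor, I: Optional[Tensor], graph: SpatialGraph) -> EmbeddingSet:
        if X.shape[1] != self.f1:
            raise ValueError(f"X has {X.shape[1]} columns, model expects {self.f1}")
        z1, alphas1 = X, []
        for layer in self.expr_layers:
            z1, a = layer.encode(z1, graph)
            alphas1.append(a)
        z2, alphas2 = None, []
        if self.multimodal:
            if I is None:
                raise ValueError("model is multimodal but no image features given")
            if I.shape[1] != self.f2:
                raise ValueError(
                    f"I has {I.shape[1]} columns, model expects {self.f2}"
                )
            z2 = I
            for layer in self.img_layers:
                z2, a = layer.encode(z2, graph)
                alphas2.append(a)
            h0 = Tensor.concat_cols(z1, z2)
        else:
            h0 = z1
        H, alpha_joint = self.joint_layer.encode(h0, graph)
        return EmbeddingSet(z1, z2, H, alphas1, alphas2, alpha_joint)

    def decode(
        self, emb: EmbeddingSet, graph: SpatialGraph
    ) -> tuple[Tensor, Optional[Tensor]]:
        h0 = self.joint_layer.decode(emb.H, emb.alpha_joint, graph)
        if self.multimodal:
            z1h = h0.cols(0, self.config.f1_latent)
            z2h = h0.cols(self.config.f1_latent, self.f_joint)
        else:
            z1h, z2h = h0, None
        for layer, alpha in zip(reversed(self.expr_layers), reversed(emb.alphas1)):
            z1h = layer.decode(z1h, alpha, graph)
        if self.multimodal:
            for layer, alpha in zip(reversed(self.img_layers), reversed(emb.alphas2)):
                z2h = layer.decode(z2h, alpha, graph)
        return z1h, z2h

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        groups = [("expr", self.expr_layers), ("img", self.img_layers)]
        for name, layers in groups:
            for i, layer in enumerate(layers):
                for pname in ("W", "v_s", "v_k"):
                    out[f"{name}.{i}.{pname}"] = getattr(layer, pname).data
        for pname in ("W", "v_s", "v_k"):
            out[f"joint.{pname}"] = getattr(self.joint_layer, pname).data
        out["discriminator.B"] = self.B.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"checkpoint missing tensors: {sorted(missing)}")
        for key, val in own.items():
            new = np.asarray(state[key], dtype=val.dtype)
            if new.shape != val.shape:
                raise ValueError(
                    f"checkpoint tensor {key}: shape {new.shape} != {val.shape}"
                )
            val[...] = new


# ---------------------------------------------------------------------------
# Contrastive components
# ---------------------------------------------------------------------------

def corrupt(
    X: np.ndarray,
    I: Optional[np.ndarray],
    rng: np.random.Generator | int | None = None,
    permutation: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, Optional[np.ndarray], np.ndarray]:
    """Row-shuffle both feature matrices with one shared permutation.

    The spatial graph is left untouched, so the negative stream pairs real
    neighborhood structure with mismatched features.  Returns
    ``(X_tilde, I_tilde, permutation)``; pass ``permutation`` to reproduce a
    recorded draw.
    """
    n = X.shape[0]
    if I is not None and I.shape[0] != n:
        raise ValueError("X and I must have equal row counts")
    if permutation is None:
        if n < 2:
            warnings.warn("corruption on n < 2 is the identity")
            permutation = np.arange(n)
        else:
            if not isinstance(rng, np.random.Generator):
                rng = np.random.default_rng(rng)
            permutation = rng.permutation(n)
    permutation = np.asarray(permutation)
    return X[permutation], None if I is None else I[permutation], permutation


def readout(H: Tensor | np.ndarray) -> Tensor:
    """Graph-level summary s = sigmoid(column-wise mean of H)."""
    H = H if isinstance(H, Tensor) else Tensor(H)
    return H.mean_rows().sigmoid()


def discriminate(H: Tensor | np.ndarray, s: Tensor | np.ndarray, B: Tensor) -> Tensor:
    """D(h_i, s) = sigmoid(h_i' B s) for every row of H; shape (n, 1)."""
    H = H if isinstance(H, Tensor) else Tensor(H)
    s = s if isinstance(s, Tensor) else Tensor(s)
    B = B if isinstance(B, Tensor) else Tensor(B)
    return (H @ B @ _col(s)).sigmoid()


def _col(s: Tensor) -> Tensor:
    # reshape (f,) -> (f, 1) keeping the tape
    from .autograd import _accum

    def back(g, a=s):
        _accum(a, g.reshape(a.data.shape))

    return Tensor._make(s.data.reshape(-1, 1), (s,), back)


def contrastive_loss(
    H: Tensor, H_neg: Tensor, s: Tensor, B: Tensor, eps: float = BCE_EPS
) -> tuple[Tensor, float, float]:
    """Binary cross-entropy over positive and negative embedding-summary pairs.

    L = -(1/2n) (sum_i log D(h_i, s) + sum_i log(1 - D(h~_i, s))), with
    probabilities clamped to [eps, 1-eps].  Also returns the mean positive
    and negative discriminator scores for monitoring.
    """
    n = H.shape[0]
    d_pos = discriminate(H, s, B).clamp(eps, 1.0 - eps)
    d_neg = discriminate(H_neg, s, B).clamp(eps, 1.0 - eps)
    loss = -(d_pos.log().sum() + (1.0 - d_neg).log().sum()) / (2.0 * n)
    return loss, float(d_pos.data.mean()), float(d_neg.data.mean())


def reconstruction_loss(
    X: np.ndarray, Xhat: Tensor, I: Optional[np.ndarray], Ihat: Optional[Tensor]
) -> Tensor:
    """Sum over spots of per-spot Euclidean errors, both modalities."""
    loss = (Tensor(X) - Xhat).row_norms().sum()
    if I is not None:
        if Ihat is None:
            raise ValueError("image features given but no image reconstruction")
        loss = loss + (Tensor(I) - Ihat).row_norms().sum()
    return loss


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Parameter], lr: float, weight_decay: float):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train(
    X: np.ndarray,
    I: Optional[np.ndarray],
    graph: SpatialGraph,
    config: RunConfig,
    epochs: Optional[int] = None,
    redraw_corruption: bool = True,
    force_contrastive_graph: bool = False,
    progress_every: int = 0,
    dtype=np.float32,
) -> tuple[GclModel, np.ndarray, LossReport]:
    """Full-batch training of the joint embedding.

    Each epoch: draw a fresh corruption (unless ``redraw_corruption`` is
    off), run the clean and corrupted streams through encoder + tied
    decoder, form L = L_GATE + beta * L_CL and take one Adam step.  With
    beta = 0 the contrastive term is skipped entirely;
    ``force_contrastive_graph`` keeps it in the computation graph anyway
    (it then contributes exactly zero gradient).  Returns the trained model,
    the final clean-stream embedding H (n x f') and the per-epoch losses.

    Array arithmetic runs in ``dtype`` (single precision by default; per-
    epoch loss scalars are always accumulated in double precision).
    """
    X = np.asarray(X, dtype=dtype)
    I = None if I is None else np.asarray(I, dtype=dtype)
    if X.shape[0] != graph.n:
        raise ValueError("X rows must match the graph size")
    epochs = config.epochs if epochs is None else epochs
    rng = np.random.default_rng(config.seed)
    model = GclModel(
        X.shape[1], None if I is None else I.shape[1], config, rng, dtype=dtype
    )
    opt = Adam(model.parameters(), config.lr, config.weight_decay)
    report = LossReport(beta=config.beta)
    use_cl = config.beta != 0 or force_contrastive_graph

    fixed_perm: Optional[np.ndarray] = None
    if not redraw_corruption:
        _, _, fixed_perm = corrupt(X, I, rng)

    for epoch in range(epochs):
        if redraw_corruption:
            Xn, In, _ = corrupt(X, I, rng)
        else:
            Xn, In, _ = corrupt(X, I, permutation=fixed_perm)

        opt.zero_grad()
        emb = model.encode(Tensor(X), None if I is None else Tensor(I), graph)
        xhat, ihat = model.decode(emb, graph)
        l_p = reconstruction_loss(X, xhat, I, ihat)

        emb_n = model.encode(Tensor(Xn), None if In is None else Tensor(In), graph)
        xhat_n, ihat_n = model.decode(emb_n, graph)
        l_n = reconstruction_loss(Xn, xhat_n, In, ihat_n)
        l_gate = l_p + l_n

        if use_cl:
            s = readout(emb.H)
            l_cl, dp, dn = contrastive_loss(emb.H, emb_n.H, s, model.B)
            total = l_gate + config.beta * l_cl
            report.l_cl.append(l_cl.item())
            report.d_pos_mean.append(dp)
            report.d_neg_mean.append(dn)
        else:
            total = l_gate
            report.l_cl.append(0.0)

        if not np.isfinite(total.item()):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: "
                f"L_GATE_P={l_p.item():.4g} L_GATE_N={l_n.item():.4g}"
            )
        report.l_gate_p.append(l_p.item())
        report.l_gate_n.append(l_n.item())
        report.l_gate.append(l_gate.item())
        report.l_total.append(total.item())

        total.backward()
        opt.step()
        if progress_every and epoch % progress_every == 0:
            log.info(
                "epoch %d: L=%.5g (gate %.5g, cl %.5g)",
                epoch, total.item(), l_gate.item(), report.l_cl[-1],
            )

    emb = model.encode(Tensor(X), None if I is None else Tensor(I), graph)
    return model, emb.H.data.copy(), report
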