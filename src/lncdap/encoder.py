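"""Multi-view graph-attention encoder with inner-product reconstruction.

Each similarity view becomes a weighted graph (edge list plus mandatory
self-loops). A dedicated stack of three graph-attention (GAT) layers
encodes every view down to 64-dimensional node features; the per-node
features are aggregated across views by an element-wise mean (with dropout
during training) into a unified feature matrix F. Training minimises the
masked squared Frobenius discrepancy between the reconstruction F @ F.T
and each view's similarity matrix,

    loss = (1/n^2) * sum_j || b_j ⊙ (F F^T − A_j) ⊙ b_j^T ||_F^2,

where b_j is view j's node mask. Attention logits follow the standard GAT
construction (shared linear map, additive edge scoring, LeakyReLU,
per-node softmax); edge weights enter the softmax as additive
log-weights, so an edge of weight w multiplies the unnormalised attention
by w.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, leaky_relu, masked_softmax
from .datatypes import SimilarityNetwork

__all__ = [
    "ViewGraph",
    "EncoderConfig",
    "EncoderState",
    "build_view_graph",
    "GATLayer",
    "gat_layer_forward",
    "reconstruction_loss",
    "reconstruction_loss_value",
    "train_encoder",
]


@dataclass
class ViewGraph:
    """One similarity view as a weighted undirected graph with self-loops."""

    n: int
    sources: np.ndarray      # int, directed edge list (both orientations stored)
    targets: np.ndarray
    weights: np.ndarray      # float in (0, 1]
    node_mask: np.ndarray    # bool, nodes present in this view
    adjacency: np.ndarray    # the full similarity matrix (reconstruction target)
    view_name: str = ""

    def dense_weights(self) -> np.ndarray:
        """Dense n x n edge-weight matrix (zero where no edge)."""
        w = np.zeros((self.n, self.n))
        w[self.sources, self.targets] = self.weights
        return w


def build_view_graph(net: SimilarityNetwork, threshold: float = 0.0,
                     node_mask: np.ndarray | None = None) -> ViewGraph:
    """Convert a similarity network to edge-list form.

    Keeps every off-diagonal entry strictly above ``threshold`` (both
    directions) and adds a unit self-loop for every masked-in node; GAT
    attention requires each node to see at least itself.
    """
    n = net.n
    if n == 0:
        raise ValueError("empty similarity network")
    mask = np.ones(n, dtype=bool) if node_mask is None else np.asarray(node_mask, dtype=bool)
    vals = net.values
    src, tgt = np.nonzero((vals > threshold) & ~np.eye(n, dtype=bool))
    keep = mask[src] & mask[tgt]
    src, tgt = src[keep], tgt[keep]
    w = vals[src, tgt]
    loops = np.flatnonzero(mask)
    sources = np.concatenate([src, loops])
    targets = np.concatenate([tgt, loops])
    weights = np.concatenate([w, np.ones(loops.size)])
    return ViewGraph(n, sources, targets, weights, mask, vals.copy(), net.view_name)


@dataclass
class EncoderConfig:
    hidden_dims: tuple[int, ...] = (256, 128, 64)
    epochs: int = 200
    learning_rate: float = 1e-3
    dropout: float = 0.5
    negative_slope: float = 0.2
    edge_threshold: float = 0.0
    seed: int = 0


class GATLayer:
    """Single-head graph-attention layer.

    Per node i the output is ``LeakyReLU(sum_j alpha_ij (h_j W))`` with
    attention ``alpha_ij`` softmax-normalised over i's in-neighbourhood;
    edge scoring is ``LeakyReLU(a_src . (h_i W) + a_dst . (h_j W))`` plus
    the edge's log-weight.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 negative_slope: float = 0.2):
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.W = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.a_src = Tensor(rng.normal(0.0, scale, size=(out_dim, 1)), requires_grad=True)
        self.a_dst = Tensor(rng.normal(0.0, scale, size=(out_dim, 1)), requires_grad=True)
        self.slope = negative_slope

    def parameters(self) -> list[Tensor]:
        return [self.W, self.a_src, self.a_dst]

    def _attend(self, H: Tensor, edge_mask: np.ndarray, log_w: np.ndarray) -> tuple[Tensor, Tensor]:
        if (~edge_mask.any(axis=1)).any():
            raise ValueError("node without incident edges; self-loops are mandatory")
        Hp = H @ self.W                                   # n x out
        s = Hp @ self.a_src                               # n x 1, score of receiver
        t = Hp @ self.a_dst                               # n x 1, score of sender
        logits = leaky_relu(s + t.T, self.slope) + Tensor(log_w)
        alpha = masked_softmax(logits, edge_mask)         # rows sum to 1
        return alpha, Hp

    def attention_coefficients(self, H: np.ndarray, edge_mask: np.ndarray,
                               log_w: np.ndarray) -> np.ndarray:
        alpha, _ = self._attend(Tensor(H), edge_mask, log_w)
        return alpha.data

    def forward(self, H: Tensor, edge_mask: np.ndarray, log_w: np.ndarray) -> Tensor:
        alpha, Hp = self._attend(H, edge_mask, log_w)
        return leaky_relu(alpha @ Hp, self.slope)


def gat_layer_forward(layer: GATLayer, graph: ViewGraph, H: np.ndarray) -> np.ndarray:
    """Run one GAT layer outside training (plain arrays in and out)."""
    mask, logw = _edge_structures(graph)
    return layer.forward(Tensor(H), mask, logw).data


def _edge_structures(graph: ViewGraph) -> tuple[np.ndarray, np.ndarray]:
    w = graph.dense_weights()
    mask = w > 0
    with np.errstate(divide="ignore"):
        log_w = np.where(mask, np.log(np.where(mask, w, 1.0)), 0.0)
    return mask, log_w


class _ViewEncoder:
    """Three stacked GAT layers for one view."""

    def __init__(self, in_dim: int, dims: tuple[int, ...], rng: np.random.Generator,
                 slope: float):
        self.layers = []
        prev = in_dim
        for d in dims:
            self.layers.append(GATLayer(prev, d, rng, slope))
            prev = d

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, H0: Tensor, edge_mask: np.ndarray, log_w: np.ndarray) -> Tensor:
        h = H0
        for layer in self.layers:
            h = layer.forward(h, edge_mask, log_w)
        return h


@dataclass
class EncoderState:
    """Result of training one entity type's multi-view encoder."""

    F: np.ndarray                 # n x 64 unified feature matrix
    loss_trace: list[float]       # evaluation-mode loss per epoch
    view_names: list[str]
    seed: int
    config: EncoderConfig = field(repr=False, default=None)
    encoders: list = field(repr=False, default=None)

    @property
    def initial_loss(self) -> float:
        return self.loss_trace[0]

    @property
    def final_loss(self) -> float:
        return min(self.loss_trace)


def encode_views(encoders: list[_ViewEncoder], graphs: list[ViewGraph],
                 inits: list[Tensor], dropout_mask: np.ndarray | None = None) -> Tensor:
    """Forward all views and aggregate per-node features by element-wise mean.

    ``dropout_mask`` (already scaled) multiplies the aggregated feature
    during training; pass None at inference for a deterministic output.
    """
    outs = []
    for enc, g, h0 in zip(encoders, graphs, inits):
        mask, logw = _edge_structures(g)
        outs.append(enc.forward(h0, mask, logw))
    F = outs[0] if len(outs) == 1 else outs[0].mean_over(outs[1:])
    if dropout_mask is not None:
        F = F * Tensor(dropout_mask)
    return F


def reconstruction_loss(F: Tensor, graphs: list[ViewGraph]) -> Tensor:
    """Masked inner-product reconstruction loss (autodiff Tensor)."""
    n = graphs[0].n
    total = None
    for g in graphs:
        outer = np.outer(g.node_mask.astype(float), g.node_mask.astype(float))
        diff = (F @ F.T - Tensor(g.adjacency)) * Tensor(outer)
        term = diff.square().sum()
        total = term if total is None else total + term
    return Tensor(1.0 / n ** 2) * total


def reconstruction_loss_value(F: np.ndarray, graphs: list[ViewGraph]) -> float:
    """Plain-array version of the reconstruction loss."""
    n = graphs[0].n
    recon = F @ F.T
    total = 0.0
    for g in graphs:
        outer = np.outer(g.node_mask, g.node_mask).astype(float)
        total += float((((recon - g.adjacency) * outer) ** 2).sum())
    return total / n ** 2


def train_encoder(graphs: list[ViewGraph], config: EncoderConfig | None = None,
                  init_features: list[np.ndarray] | None = None) -> EncoderState:
    """Train the per-view GAT stacks against the reconstruction loss.

    Initial node features default to each node's row of its view's
    similarity matrix. Best-iterate checkpointing over the evaluation-mode
    (dropout-free) loss guarantees the returned F never scores worse than
    the initial one; fully deterministic for a fixed config seed.
    """
    if not graphs:
        raise ValueError("at least one view is required")
    n = graphs[0].n
    if any(g.n != n for g in graphs):
        raise ValueError("all views must share the same node count")
    config = config or EncoderConfig()
    rng = np.random.default_rng(config.seed)
    if init_features is None:
        init_features = [g.adjacency for g in graphs]
    inits = [Tensor(h) for h in init_features]
    encoders = [
        _ViewEncoder(h.shape[1], config.hidden_dims, rng, config.negative_slope)
        for h in inits
    ]
    params = [p for e in encoders for p in e.parameters()]
    opt = Adam(params, lr=config.learning_rate)

    def eval_F() -> np.ndarray:
        return encode_views(encoders, graphs, inits, dropout_mask=None).data

    best_F = eval_F()
    best_loss = reconstruction_loss_value(best_F, graphs)
    trace = [best_loss]
    for epoch in range(config.epochs):
        if config.dropout > 0:
            keep = rng.random((n, config.hidden_dims[-1])) >= config.dropout
            drop = keep.astype(float) / (1.0 - config.dropout)
        else:
            drop = None
        F = encode_views(encoders, graphs, inits, dropout_mask=drop)
        loss = reconstruction_loss(F, graphs)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite reconstruction loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        F_eval = eval_F()
        eval_loss = reconstruction_loss_value(F_eval, graphs)
        trace.append(eval_loss)
        if eval_loss < best_loss:
            best_loss = eval_loss
            best_F = F_eval
    return EncoderState(F=best_F, loss_trace=trace,
                        view_names=[g.view_name for g in graphs],
                        seed=config.seed, config=config, encoders=encoders)
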