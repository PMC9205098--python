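"""LINE graph embedding: first- and second-order proximity with negative
sampling, trained by SGD over alias-sampled edges.

First-order proximity models the joint probability of a directly connected
pair as sigma(v_i . v_j).  Second-order proximity models the conditional
distribution of a node's neighbours with a softmax over context vectors, so
nodes with similar neighbourhoods land close together even without a mutual
edge.  Both objectives are optimised with the standard negative-sampling
surrogate: each observed edge is contrasted against K noise nodes drawn
with probability proportional to degree^0.75.

The heterogeneous molecular network is embedded as an unweighted,
undirected, untyped graph; the two orders are trained separately and their
vertex vectors concatenated into the intra-view protein feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hetnet import HeteroNetwork, NodeRef

__all__ = [
    "LineConfig",
    "EmbeddingTable",
    "AliasSampler",
    "EdgeSampler",
    "NoiseSampler",
    "first_order_proximity",
    "second_order_conditional",
    "negative_sampling_loss",
    "negative_sampling_grads",
    "build_edge_sampler",
    "build_noise_sampler",
    "train_line",
    "intra_view_features",
    "write_embedding_table",
]


@dataclass(frozen=True)
class LineConfig:
    """Training hyperparameters.

    dim_per_order
        Length of each order's vertex vector; the intra-view feature is the
        two concatenated, hence 2*dim_per_order long.
    negative_samples
        Noise nodes K contrasted against each positive edge draw.
    initial_learning_rate
        SGD step size; decays linearly to 1e-4 of its initial value.
    total_samples
        Edge draws per order; ``None`` means 100 * |edges|.
    noise_exponent
        Degree power of the noise distribution (0.75 is the classic choice;
        0 gives a uniform noise distribution).
    """

    dim_per_order: int = 64
    negative_samples: int = 5
    initial_learning_rate: float = 0.025
    total_samples: int | None = None
    noise_exponent: float = 0.75
    seed: int = 0
    batch_size: int = 1024

    def __post_init__(self) -> None:
        if self.dim_per_order < 1:
            raise ValueError("dim_per_order must be >= 1")
        if self.negative_samples < 1:
            raise ValueError("negative_samples must be >= 1")
        if self.initial_learning_rate <= 0:
            raise ValueError("initial_learning_rate must be > 0")
        if self.total_samples is not None and self.total_samples < 1:
            raise ValueError("total_samples must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EmbeddingTable:
    """Per-node vertex vectors plus the context vectors of the second-order
    role ('the node itself' vs 'a neighbour of other nodes')."""

    nodes: tuple[NodeRef, ...]
    vertex: np.ndarray  # (n, d)
    context: np.ndarray  # (n, d)
    index: dict[NodeRef, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {n: i for i, n in enumerate(self.nodes)}
        if self.vertex.shape != self.context.shape or self.vertex.shape[0] != len(self.nodes):
            raise ValueError("vertex/context shape mismatch with node list")

    @property
    def dim(self) -> int:
        return self.vertex.shape[1]

    def vector(self, node: NodeRef) -> np.ndarray:
        return self.vertex[self.index[node]]

    def context_vector(self, node: NodeRef) -> np.ndarray:
        return self.context[self.index[node]]


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def first_order_proximity(u_vec: np.ndarray, v_vec: np.ndarray) -> float:
    """Joint probability sigma(u . v) of a directly connected pair;
    symmetric in its arguments and strictly inside (0, 1)."""
    u_vec = np.asarray(u_vec, dtype=float)
    v_vec = np.asarray(v_vec, dtype=float)
    if u_vec.shape != v_vec.shape:
        raise ValueError(f"vector length mismatch: {u_vec.shape} vs {v_vec.shape}")
    return float(_sigmoid(float(u_vec @ v_vec)))


def second_order_conditional(i: NodeRef, j: NodeRef, table: EmbeddingTable) -> float:
    """Exact softmax P(i | j) = exp(c_i . v_j) / sum_k exp(c_k . v_j) over
    all context vectors.  This is the training target that SGD approximates
    by negative sampling."""
    for node in (i, j):
        if node not in table.index:
            raise KeyError(f"node {node} not in embedding table")
    logits = table.context @ table.vertex[table.index[j]]
    logits -= logits.max()  # stability
    weights = np.exp(logits)
    return float(weights[table.index[i]] / weights.sum())


def negative_sampling_loss(
    u_vec: np.ndarray, pos_vec: np.ndarray, neg_vecs: np.ndarray
) -> float:
    """Negative-sampling objective for one positive pair and K noise rows:
    -log sigma(pos.u) - sum_k log sigma(-neg_k.u)."""
    u_vec = np.asarray(u_vec, dtype=float)
    pos = float(np.log(_sigmoid(np.dot(pos_vec, u_vec))))
    neg = float(np.sum(np.log(_sigmoid(-np.asarray(neg_vecs) @ u_vec))))
    return -(pos + neg)


def negative_sampling_grads(
    u_vec: np.ndarray, pos_vec: np.ndarray, neg_vecs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`negative_sampling_loss` w.r.t. the
    source vector, the positive target and each noise target."""
    u_vec = np.asarray(u_vec, dtype=float)
    pos_vec = np.asarray(pos_vec, dtype=float)
    neg_vecs = np.asarray(neg_vecs, dtype=float)
    g_pos_scalar = _sigmoid(np.dot(pos_vec, u_vec)) - 1.0  # d/d(pos.u)
    g_neg_scalar = _sigmoid(neg_vecs @ u_vec)  # d/d(neg_k.u)
    grad_u = g_pos_scalar * pos_vec + g_neg_scalar @ neg_vecs
    grad_pos = g_pos_scalar * u_vec
    grad_negs = g_neg_scalar[:, None] * u_vec[None, :]
    return grad_u, grad_pos, grad_negs


class AliasSampler:
    """Constant-time sampling from a fixed discrete distribution
    (Vose's alias method)."""

    def __init__(self, probs: Sequence[float]) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or len(probs) == 0:
            raise ValueError("probs must be a non-empty 1-d array")
        if np.any(probs < 0) or probs.sum() <= 0:
            raise ValueError("probs must be non-negative with positive sum")
        n = len(probs)
        scaled = probs * (n / probs.sum())
        self.prob = np.zeros(n)
        self.alias = np.zeros(n, dtype=np.int64)
        small = [i for i, p in enumerate(scaled) if p < 1.0]
        large = [i for i, p in enumerate(scaled) if p >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            self.prob[s] = scaled[s]
            self.alias[s] = l
            scaled[l] = (scaled[l] + scaled[s]) - 1.0
            (small if scaled[l] < 1.0 else large).append(l)
        for i in small + large:
            self.prob[i] = 1.0

    def draw(self, rng: np.random.Generator, size: int | tuple = 1) -> np.ndarray:
        idx = rng.integers(0, len(self.prob), size=size)
        accept = rng.random(size=size) < self.prob[idx]
        return np.where(accept, idx, self.alias[idx])


class EdgeSampler:
    """Uniform sampler over the (undirected) edges of a network."""

    def __init__(self, net: HeteroNetwork, seed: int | None = None) -> None:
        if not net.edges:
            raise ValueError("network has no edges to sample")
        self.edges = tuple(sorted(net.edges, key=lambda e: (e.u, e.v, e.relation)))
        self._alias = AliasSampler(np.ones(len(self.edges)))
        self._rng = np.random.default_rng(seed)

    def draw(self, size: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or self._rng
        idx = self._alias.draw(rng, size=size if size is not None else 1)
        if size is None:
            return self.edges[int(idx[0])]
        return [self.edges[int(i)] for i in np.atleast_1d(idx)]


class NoiseSampler:
    """Node sampler with P(i) proportional to degree(i)^exponent; nodes of
    zero degree are never drawn (for exponent > 0)."""

    def __init__(self, net: HeteroNetwork, exponent: float = 0.75, seed: int | None = None) -> None:
        if not net.edges:
            raise ValueError("network has no edges; noise distribution undefined")
        self.nodes = tuple(sorted(net.nodes))
        degrees = np.array([net.degree(n) for n in self.nodes], dtype=float)
        with np.errstate(divide="ignore"):
            weights = degrees**exponent
        weights[degrees == 0] = 0.0 if exponent > 0 else weights[degrees == 0]
        if exponent == 0:
            weights = np.ones_like(degrees)
        self._alias = AliasSampler(weights)
        self._rng = np.random.default_rng(seed)

    def draw(self, size: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or self._rng
        idx = self._alias.draw(rng, size=size if size is not None else 1)
        if size is None:
            return self.nodes[int(idx[0])]
        return [self.nodes[int(i)] for i in np.atleast_1d(idx)]


def build_edge_sampler(net: HeteroNetwork, seed: int | None = None) -> EdgeSampler:
    return EdgeSampler(net, seed)


def build_noise_sampler(
    net: HeteroNetwork, exponent: float = 0.75, seed: int | None = None
) -> NoiseSampler:
    return NoiseSampler(net, exponent, seed)


def _init_vectors(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    return (rng.random((n, dim)) - 0.5) / dim


def _train_order(
    order: int,
    src: np.ndarray,
    dst: np.ndarray,
    noise_alias: AliasSampler,
    n_nodes: int,
    cfg: LineConfig,
    total: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``total`` negative-sampling SGD draws for one proximity order.

    First order updates vertex vectors on both sides; second order pairs the
    source's vertex vector with target context vectors.  Draws are processed
    in synchronous mini-batches (gradients evaluated at the pre-update
    parameters, accumulated with scatter-add), which keeps the run exactly
    reproducible for a given seed.
    """
    dim, K = cfg.dim_per_order, cfg.negative_samples
    vertex = _init_vectors(rng, n_nodes, dim)
    context = np.zeros((n_nodes, dim)) if order == 2 else _init_vectors(rng, n_nodes, dim)
    edge_alias = AliasSampler(np.ones(len(src)))
    lr0 = cfg.initial_learning_rate
    # Synchronous batching approximates sequential SGD only while each node
    # collects few updates per batch; capping the batch at |V| keeps the
    # accumulated per-node step small enough to preserve the sequential
    # dynamics' self-stabilisation (large stale batches diverge on small
    # graphs).
    batch = min(cfg.batch_size, n_nodes)
    done = 0
    while done < total:
        b = min(batch, total - done)
        lr = lr0 * max(1.0 - done / total, 1e-4)
        e_idx = edge_alias.draw(rng, size=b)
        u_idx, v_idx = src[e_idx], dst[e_idx]
        n_idx = noise_alias.draw(rng, size=(b, K))
        u = vertex[u_idx]  # (b, d) source vertex vectors
        target = vertex if order == 1 else context
        pos = target[v_idx]
        neg = target[n_idx]  # (b, K, d)
        g_pos = _sigmoid(np.einsum("bd,bd->b", pos, u)) - 1.0  # (b,)
        g_neg = _sigmoid(np.einsum("bkd,bd->bk", neg, u))  # (b, K)
        grad_u = g_pos[:, None] * pos + np.einsum("bk,bkd->bd", g_neg, neg)
        grad_pos = g_pos[:, None] * u
        grad_neg = g_neg[..., None] * u[:, None, :]
        np.add.at(vertex, u_idx, -lr * grad_u)
        np.add.at(target, v_idx, -lr * grad_pos)
        np.add.at(target, n_idx.ravel(), -lr * grad_neg.reshape(-1, dim))
        done += b
    return vertex, context


def train_line(
    net: HeteroNetwork, config: LineConfig = LineConfig()
) -> tuple[EmbeddingTable, EmbeddingTable]:
    """Train first- and second-order embeddings on a network.

    Returns the two orders as separate tables.  Each undirected edge is
    entered in both directions; edge and node types are ignored.  Isolated
    nodes are never drawn and keep their (finite) initialisation.
    """
    if not net.edges:
        raise ValueError("network must have at least one edge")
    nodes = tuple(sorted(net.nodes))
    index = {n: i for i, n in enumerate(nodes)}
    und = sorted(net.edges, key=lambda e: (e.u, e.v, e.relation))
    src = np.array([index[e.u] for e in und] + [index[e.v] for e in und])
    dst = np.array([index[e.v] for e in und] + [index[e.u] for e in und])
    degrees = np.array([net.degree(n) for n in nodes], dtype=float)
    weights = np.where(degrees > 0, degrees, 0.0) ** config.noise_exponent if config.noise_exponent != 0 else np.ones_like(degrees)
    noise_alias = AliasSampler(weights)
    total = config.total_samples if config.total_samples is not None else 100 * len(und)
    rng = np.random.default_rng(config.seed)
    tables = []
    for order in (1, 2):
        vertex, context = _train_order(
            order, src, dst, noise_alias, len(nodes), config, total, rng
        )
        tables.append(EmbeddingTable(nodes, vertex, context))
    first, second = tables
    return first, second


def intra_view_features(
    first: EmbeddingTable,
    second: EmbeddingTable,
    nodes: Iterable[NodeRef],
) -> dict[NodeRef, np.ndarray]:
    """Concatenate first- then second-order vertex vectors per node;
    each output has length 2*dim_per_order."""
    out: dict[NodeRef, np.ndarray] = {}
    for node in nodes:
        if node not in first.index or node not in second.index:
            raise KeyError(f"node {node} missing from embedding tables")
        out[node] = np.concatenate([first.vector(node), second.vector(node)])
    return out


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(table.vertex, columns=[f"e{i:03d}" for i in range(table.dim)])
    df.insert(0, "node_id", [n.id for n in table.nodes])
    df.insert(1, "node_type", [n.ntype for n in table.nodes])
    df.to_csv(path, sep="\t", index=False)
    return path
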