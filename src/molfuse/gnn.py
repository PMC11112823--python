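"""Graph convolution (GCN) and dynamic graph attention (GATv2) layers.

GCN implements the first-order spectral convolution
``H' = sigma(D^{-1/2} (A+I) D^{-1/2} H W)`` with self-loops added and symmetric
degree normalization. GATv2 scores each directed edge (j -> i, self-loop
included) as ``e_ij = a^T LeakyReLU(W_l h_i + W_r h_j [+ W_e x_ij])``,
normalizes scores over every node's in-neighborhood with a softmax, and
updates ``h_i' = sigma(sum_j alpha_ij W_r h_j)``; multiple heads concatenate.
GCN ignores edge features (its cited form is nodes-only); GATv2 mixes an edge
feature embedding into the score by default — both are toggles.

Layers run on a whole batch at once: disjoint molecular graphs are stacked
into one block-diagonal union graph, so these functions only ever see a single
edge list. Attention normalization uses a dense node-by-edge incidence matrix,
which is cheap at molecular scale.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Linear, Module, Parameter, Tensor, _glorot
from .exceptions import ShapeError

__all__ = ["normalized_adjacency", "add_self_loops", "GCNLayer", "GATv2Layer"]


def add_self_loops(edge_index: np.ndarray, num_nodes: int,
                   edge_features: np.ndarray | None = None):
    """Append (i, i) edges; self-loop edge features are zero rows."""
    loops = np.arange(num_nodes, dtype=np.int64)
    ei = np.concatenate([edge_index,
                         np.stack([loops, loops])], axis=1)
    if edge_features is None:
        return ei, None
    ef = np.concatenate(
        [edge_features,
         np.zeros((num_nodes, edge_features.shape[1]),
                  dtype=edge_features.dtype)], axis=0)
    return ei, ef


def normalized_adjacency(edge_index: np.ndarray, num_nodes: int,
                         dtype=np.float64) -> np.ndarray:
    """Dense symmetric-normalized adjacency with self-loops: D̃^-1/2 Ã D̃^-1/2."""
    a = np.zeros((num_nodes, num_nodes), dtype=dtype)
    if edge_index.size:
        a[edge_index[1], edge_index[0]] = 1.0
    a[np.arange(num_nodes), np.arange(num_nodes)] = 1.0
    deg = a.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


_ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "identity": lambda t: t,
    "tanh": lambda t: t.tanh(),
    "leaky_relu": lambda t: t.leaky_relu(0.2),
}


class GCNLayer(Module):
    """One graph-convolution layer over a (batched) molecular graph."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str = "relu", dtype=np.float32):
        super().__init__()
        self.W = Parameter(_glorot(rng, d_in, d_out, (d_in, d_out), dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype))
        self.activation = activation

    def forward(self, h: Tensor, a_hat: np.ndarray) -> Tensor:
        if h.shape[-1] != self.W.shape[0]:
            raise ShapeError(f"GCN input width {h.shape[-1]} != "
                             f"{self.W.shape[0]}")
        if a_hat.shape[0] != h.shape[0]:
            raise ShapeError("adjacency size does not match node count")
        out = Tensor(a_hat.astype(h.data.dtype, copy=False)) @ (h @ self.W)
        return _ACTIVATIONS[self.activation](out + self.b)

    __call__ = forward


class GATv2Layer(Module):
    """One GATv2 attention layer (self-loops included, heads concatenated)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 heads: int = 1, negative_slope: float = 0.2,
                 edge_dim: int | None = None, activation: str = "relu",
                 dtype=np.float32):
        super().__init__()
        self.heads = heads
        self.d_out = d_out
        self.negative_slope = negative_slope
        self.Wl = Parameter(_glorot(rng, d_in, heads * d_out,
                                    (d_in, heads * d_out), dtype))
        self.Wr = Parameter(_glorot(rng, d_in, heads * d_out,
                                    (d_in, heads * d_out), dtype))
        self.att = Parameter(_glorot(rng, d_out, 1, (heads, d_out), dtype))
        self.We = (Parameter(_glorot(rng, edge_dim, heads * d_out,
                                     (edge_dim, heads * d_out), dtype))
                   if edge_dim else None)
        self.b = Parameter(np.zeros(heads * d_out, dtype=dtype))
        self.activation = activation

    def forward(self, h: Tensor, edge_index: np.ndarray,
                edge_features: np.ndarray | None = None,
                num_nodes: int | None = None):
        """Returns (updated node matrix [N, heads*d_out], alpha [E, heads]).

        ``edge_index`` must already contain self-loops (see
        :func:`add_self_loops`); edge (src=j, dst=i) carries a message j→i.
        """
        if h.shape[-1] != self.Wl.shape[0]:
            raise ShapeError(f"GATv2 input width {h.shape[-1]} != "
                             f"{self.Wl.shape[0]}")
        n = num_nodes if num_nodes is not None else h.shape[0]
        src, dst = edge_index
        n_edges = src.shape[0]
        hl = (h @ self.Wl)[dst]                      # [E, H*D] receiver part
        hr_all = h @ self.Wr
        hr = hr_all[src]                             # [E, H*D] sender part
        z = hl + hr
        if self.We is not None and edge_features is not None:
            z = z + Tensor(edge_features.astype(h.data.dtype,
                                                copy=False)) @ self.We
        z = z.leaky_relu(self.negative_slope)
        z = z.reshape(n_edges, self.heads, self.d_out)
        scores = (z * self.att).sum(axis=-1)         # [E, H]
        # softmax over each node's in-edges via a dense incidence matrix
        inc = np.zeros((n, n_edges), dtype=h.data.dtype)
        inc[dst, np.arange(n_edges)] = 1.0
        # per-destination max for numerical stability (constant shift)
        smax = np.full((n, self.heads), -np.inf, dtype=scores.data.dtype)
        np.maximum.at(smax, dst, scores.data)
        e = (scores - Tensor(smax[dst])).exp()
        denom = Tensor(inc) @ e                      # [N, H]
        alpha = e / denom[dst]
        messages = (alpha.reshape(n_edges, self.heads, 1)
                    * hr.reshape(n_edges, self.heads, self.d_out))
        messages = messages.reshape(n_edges, self.heads * self.d_out)
        out = Tensor(inc) @ messages + self.b
        return _ACTIVATIONS[self.activation](out), alpha

    __call__ = forward
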