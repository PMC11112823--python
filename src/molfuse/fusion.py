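"""The fused language+graph property model and its ablations.

Architecture: a language encoder produces per-token embeddings under the
heavy-atom attention mask; each mapped token embedding is concatenated onto
the node feature row of the heavy atom it aligns to; a linear projection
reduces the concatenation to the GNN hidden width; a stack of GCN or GATv2
layers passes messages; mean pooling over nodes feeds a dense head with
dropout. Ablations remove one branch: GRAPH_ONLY never invokes the encoder,
LANGUAGE_ONLY pools the masked token embeddings directly into the head.

Molecules are batched as one disjoint-union graph (block-diagonal adjacency),
with a padded token-id matrix for the encoder and a flat token-row index per
node realizing the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import scipy.linalg

from ._tensor import Linear, Module, Tensor, cat, dropout
from .alignment import AlignmentMap, align_tokens_to_nodes
from .encoder import TinyTransformerEncoder
from .exceptions import AlignmentError, ModeError
from .gnn import GATv2Layer, GCNLayer, add_self_loops, normalized_adjacency
from .molgraph import (DEFAULT_SCHEMA, FeatureSchema, MolGraph, Molecule,
                       featurize_graph, parse_smiles)
from .tokenization import TokenizerSpec, TokenSequence, tokenize

__all__ = ["Mode", "ArchConfig", "PreparedMolecule", "Batch", "FusionModel",
           "prepare_molecule", "collate", "fuse_features", "make_ablation"]


class Mode(str, Enum):
    FUSED = "fused"
    GRAPH_ONLY = "graph"
    LANGUAGE_ONLY = "language"


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters with documented defaults.

    The source method leaves GNN depth/width and readout unstated; defaults
    here are 3 layers of width 128 with mean pooling. Test-scale runs shrink
    these explicitly.
    """

    gnn_type: str = "gatv2"            # "gcn" | "gatv2"
    hidden: int = 128
    n_gnn_layers: int = 3
    heads: int = 1
    d_lang: int = 16
    n_lang_layers: int = 2
    dropout: float = 0.2
    readout: str = "mean"              # "mean" | "sum" | "max"
    use_edge_features: bool = True     # GATv2 only; GCN is nodes-only
    negative_slope: float = 0.2

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class PreparedMolecule:
    """A molecule with every representation the model needs, computed once."""

    smiles: str
    molecule: Molecule
    graph: MolGraph
    tokens: TokenSequence
    amap: AlignmentMap
    label: float | None = None


def prepare_molecule(smiles: str, schema: FeatureSchema = DEFAULT_SCHEMA,
                     tok_spec: TokenizerSpec | None = None,
                     label: float | None = None) -> PreparedMolecule:
    from .tokenization import default_tokenizer_spec
    tok_spec = tok_spec or default_tokenizer_spec()
    molecule = parse_smiles(smiles)
    graph = featurize_graph(molecule, schema)
    seq = tokenize(smiles, tok_spec)
    amap = align_tokens_to_nodes(seq, molecule)
    return PreparedMolecule(smiles=smiles, molecule=molecule, graph=graph,
                            tokens=seq, amap=amap, label=label)


@dataclass
class Batch:
    """Disjoint-union batch of prepared molecules."""

    size: int
    node_features: np.ndarray          # [N, d_node]
    a_hat: np.ndarray                  # [N, N] normalized adjacency
    edge_index_sl: np.ndarray          # [2, E'] with self-loops
    edge_features_sl: np.ndarray       # [E', d_edge]
    pool: np.ndarray                   # [B, N] readout matrix
    token_ids: np.ndarray              # [B, T] padded
    attention_mask: np.ndarray         # [B, T]
    node_token_row: np.ndarray         # [N] flat index into [B*T] token rows
    lang_pool: np.ndarray              # [B, B*T] masked mean-pool matrix
    labels: np.ndarray | None
    mode: Mode


def collate(records: list[PreparedMolecule], pad_id: int,
            mode: Mode = Mode.FUSED, readout: str = "mean",
            dtype=np.float32) -> Batch:
    """Stack prepared molecules into one batch."""
    B = len(records)
    if B == 0:
        raise ModeError("cannot collate an empty batch")
    T = max(len(r.tokens) for r in records)
    sizes = [r.graph.num_nodes for r in records]
    N = int(sum(sizes))
    node_features = np.concatenate([r.graph.node_features for r in records])
    a_hat = scipy.linalg.block_diag(
        *[normalized_adjacency(r.graph.edge_index, r.graph.num_nodes,
                               dtype=dtype) for r in records])
    offsets = np.cumsum([0] + sizes)

    ei_parts, ef_parts = [], []
    for r, off in zip(records, offsets[:-1]):
        ei, ef = add_self_loops(r.graph.edge_index, r.graph.num_nodes,
                                r.graph.edge_features)
        ei_parts.append(ei + off)
        ef_parts.append(ef)
    edge_index_sl = np.concatenate(ei_parts, axis=1)
    edge_features_sl = np.concatenate(ef_parts, axis=0).astype(dtype)

    pool = np.zeros((B, N), dtype=dtype)
    for b, (off, n) in enumerate(zip(offsets[:-1], sizes)):
        pool[b, off:off + n] = (1.0 / n) if readout == "mean" else 1.0

    token_ids = np.full((B, T), pad_id, dtype=np.int64)
    attention_mask = np.zeros((B, T), dtype=np.int64)
    node_token_row = np.zeros(N, dtype=np.int64)
    lang_pool = np.zeros((B, B * T), dtype=dtype)
    for b, r in enumerate(records):
        L = len(r.tokens)
        token_ids[b, :L] = r.tokens.ids
        attention_mask[b, :L] = r.amap.attention_mask
        t_for_n = r.amap.token_for_node()
        for local_node, tok_pos in t_for_n.items():
            node_token_row[offsets[b] + local_node] = b * T + tok_pos
        n_attended = max(len(t_for_n), 1)
        for tok_pos in set(t_for_n.values()):
            lang_pool[b, b * T + tok_pos] = 1.0 / n_attended

    labels = None
    if all(r.label is not None for r in records):
        labels = np.asarray([r.label for r in records], dtype=np.float64)
    return Batch(size=B, node_features=node_features.astype(dtype),
                 a_hat=a_hat, edge_index_sl=edge_index_sl,
                 edge_features_sl=edge_features_sl, pool=pool,
                 token_ids=token_ids, attention_mask=attention_mask,
                 node_token_row=node_token_row, lang_pool=lang_pool,
                 labels=labels, mode=mode)


def fuse_features(graph: MolGraph, token_embeddings,
                  amap: AlignmentMap) -> Tensor:
    """Concatenate mapped token embeddings onto node feature rows.

    Row k of the output is [node_features[k] ‖ token_embeddings[t(k)]] where
    t(k) is the token position mapped to node k. Shape
    [num_nodes, d_node + d_L]. Only mapped token rows are read.
    """
    emb = token_embeddings if isinstance(token_embeddings, Tensor) \
        else Tensor(np.asarray(token_embeddings))
    if amap.num_nodes != graph.num_nodes:
        raise AlignmentError(
            f"alignment covers {amap.num_nodes} nodes, graph has "
            f"{graph.num_nodes}")
    if emb.shape[0] < max((tok for tok, _ in amap.pairs), default=-1) + 1:
        raise AlignmentError("token embedding matrix shorter than alignment")
    t_for_n = amap.token_for_node()
    rows = np.asarray([t_for_n[k] for k in range(graph.num_nodes)])
    node_feats = Tensor(graph.node_features.astype(emb.data.dtype))
    return cat([node_feats, emb[rows]], axis=-1)


class FusionModel(Module):
    """Language+graph fusion model with ablation modes.

    Parameters are created from ``seed``; two models built with the same
    arguments are bit-identical.
    """

    def __init__(self, task, d_node: int, mode: Mode | str = Mode.FUSED,
                 arch: ArchConfig = ArchConfig(), vocab_size: int = 128,
                 d_edge: int | None = None, seed: int = 0,
                 max_len: int = 512, dtype=np.float32):
        super().__init__()
        self.task = task
        self.mode = Mode(mode)
        self.arch = arch
        self.d_node = d_node
        self.d_edge = d_edge
        self.vocab_size = vocab_size
        self.seed = seed
        self.max_len = max_len
        rng = np.random.default_rng(seed + 1)

        self.encoder = None
        if self.mode in (Mode.FUSED, Mode.LANGUAGE_ONLY):
            self.encoder = TinyTransformerEncoder(
                vocab_size, d_model=arch.d_lang,
                n_layers=arch.n_lang_layers, max_len=max_len, seed=seed,
                dtype=dtype)

        h = arch.hidden
        if self.mode is Mode.FUSED:
            d_in = d_node + arch.d_lang
        elif self.mode is Mode.GRAPH_ONLY:
            d_in = d_node
        else:
            d_in = arch.d_lang
        self.proj = Linear(d_in, h, rng, dtype=dtype)

        self.gnn_layers = []
        if self.mode is not Mode.LANGUAGE_ONLY:
            for _ in range(arch.n_gnn_layers):
                if arch.gnn_type == "gcn":
                    self.gnn_layers.append(
                        GCNLayer(h, h, rng, dtype=dtype))
                elif arch.gnn_type == "gatv2":
                    self.gnn_layers.append(GATv2Layer(
                        h, h // arch.heads, rng, heads=arch.heads,
                        negative_slope=arch.negative_slope,
                        edge_dim=(d_edge if arch.use_edge_features else None),
                        dtype=dtype))
                else:
                    raise ModeError(f"unknown gnn_type {arch.gnn_type!r}")

        self.head1 = Linear(h, h, rng, dtype=dtype)
        self.head2 = Linear(h, 1, rng, dtype=dtype)
        self._dropout_rng = np.random.default_rng(seed + 2)

    def reseed_dropout(self, seed: int) -> None:
        """Reset the dropout stream (called by the training loop)."""
        self._dropout_rng = np.random.default_rng(seed)

    # ------------------------------------------------------------------
    def _node_input(self, batch: Batch) -> Tensor:
        node_feats = Tensor(batch.node_features)
        if self.mode is Mode.GRAPH_ONLY:
            return node_feats
        emb = self.encoder.embed(batch.token_ids, batch.attention_mask)
        flat = emb.reshape(emb.shape[0] * emb.shape[1], emb.shape[2])
        tok_rows = flat[batch.node_token_row]
        return cat([node_feats, tok_rows], axis=-1)

    def forward(self, batch: Batch,
                return_embedding: bool = False):
        """Predictions for a batch (one value per molecule, order preserved).

        Regression returns raw values; classification returns probabilities
        through a logistic output. With ``return_embedding`` the penultimate
        dense-layer activation is returned alongside.
        """
        if batch.mode != self.mode:
            raise ModeError(f"batch prepared for mode {batch.mode}, model is "
                            f"{self.mode}")
        if self.mode is Mode.LANGUAGE_ONLY:
            emb = self.encoder.embed(batch.token_ids, batch.attention_mask)
            flat = emb.reshape(emb.shape[0] * emb.shape[1], emb.shape[2])
            pooled = Tensor(batch.lang_pool.astype(flat.data.dtype)) @ flat
            x = self.proj(pooled)
        else:
            h = self.proj(self._node_input(batch))
            for layer in self.gnn_layers:
                if isinstance(layer, GCNLayer):
                    h = layer(h, batch.a_hat)
                else:
                    h, _ = layer(h, batch.edge_index_sl,
                                 batch.edge_features_sl)
            x = Tensor(batch.pool.astype(h.data.dtype)) @ h
        penultimate = self.head1(x).relu()
        z = dropout(penultimate, self.arch.dropout, self._dropout_rng,
                    self.training)
        out = self.head2(z).reshape(batch.size)
        if getattr(self.task, "task_type", "regression") == "classification":
            out = out.sigmoid()
        if return_embedding:
            return out, penultimate
        return out

    __call__ = forward

    def encoder_parameters(self):
        return self.encoder.parameters() if self.encoder is not None else []

    def coder_parameters(self):
        """All parameters outside the language encoder (graph + head)."""
        enc = {id(p) for p in self.encoder_parameters()}
        return [p for p in self.parameters() if id(p) not in enc]


def make_ablation(model: FusionModel, mode: Mode | str) -> FusionModel:
    """A freshly initialized model with one branch removed.

    Shares task, architecture hyperparameters, and seed with the donor; the
    named branch is absent so the parameter count is strictly smaller.
    """
    mode = Mode(mode)
    if mode is Mode.FUSED:
        raise ModeError("ablation must remove a branch; FUSED removes none")
    return FusionModel(task=model.task, d_node=model.d_node, mode=mode,
                       arch=model.arch, vocab_size=model.vocab_size,
                       d_edge=model.d_edge, seed=model.seed,
                       max_len=model.max_len)
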