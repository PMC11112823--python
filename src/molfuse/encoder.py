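"""Language encoders producing per-token embeddings.

The encoder interface is intentionally small so that externally trained
chemical language models can be plugged in: ``embed(ids, attention_mask)``
returns a per-token embedding matrix, ``layer_count`` reports the number of
transformer blocks, and ``freeze(first_n)`` excludes the embedding tables and
the first n blocks from gradient updates.

:class:`TinyTransformerEncoder` is the shipped default — a token-embedding
table plus a small stack of pre-norm transformer blocks, randomly initialized
from a seed. It keeps the package trainable end-to-end with no downloads.
:class:`TableEncoder` wraps an externally produced per-token embedding matrix
(e.g. exported from a pretrained model) behind the same interface.
"""

from __future__ import annotations

import numpy as np

from ._tensor import (LayerNorm, Linear, Module, Parameter, Tensor, dropout,
                      softmax_lastdim)
from .exceptions import DomainError

__all__ = ["TinyTransformerEncoder", "TableEncoder"]


class _SelfAttention(Module):
    def __init__(self, d: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.q = Linear(d, d, rng, dtype=dtype)
        self.k = Linear(d, d, rng, dtype=dtype)
        self.v = Linear(d, d, rng, dtype=dtype)
        self.o = Linear(d, d, rng, dtype=dtype)
        self.scale = 1.0 / np.sqrt(d)

    def forward(self, x: Tensor, attention_mask: np.ndarray) -> Tensor:
        # attention_mask [B, T]: 0-keys are excluded for every query
        q, k, v = self.q(x), self.k(x), self.v(x)
        scores = q @ k.swapaxes(-1, -2) * self.scale            # [B, T, T]
        bias = np.where(attention_mask[:, None, :] > 0, 0.0,
                        -1e9).astype(x.data.dtype)
        att = softmax_lastdim(scores, additive_mask=bias)
        return self.o(att @ v)

    __call__ = forward


class _Block(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.ln1 = LayerNorm(d, dtype=dtype)
        self.attn = _SelfAttention(d, rng, dtype=dtype)
        self.ln2 = LayerNorm(d, dtype=dtype)
        self.ff1 = Linear(d, d_ff, rng, dtype=dtype)
        self.ff2 = Linear(d_ff, d, rng, dtype=dtype)

    def forward(self, x: Tensor, attention_mask: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), attention_mask)
        return x + self.ff2(self.ff1(self.ln2(x)).relu())

    __call__ = forward


class TinyTransformerEncoder(Module):
    """Small randomly initialized transformer over SMILES tokens."""

    def __init__(self, vocab_size: int, d_model: int = 16, n_layers: int = 2,
                 d_ff: int | None = None, max_len: int = 512, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(seed)
        d_ff = d_ff or 2 * d_model
        self.d_model = d_model
        scale = 1.0 / np.sqrt(d_model)
        self.tok_embed = Parameter(
            (rng.standard_normal((vocab_size, d_model)) * scale).astype(dtype))
        self.pos_embed = Parameter(
            (rng.standard_normal((max_len, d_model)) * scale).astype(dtype))
        self.blocks = [_Block(d_model, d_ff, rng, dtype=dtype)
                       for _ in range(n_layers)]
        self.ln_final = LayerNorm(d_model, dtype=dtype)

    @property
    def layer_count(self) -> int:
        return len(self.blocks)

    @property
    def d_out(self) -> int:
        return self.d_model

    def freeze(self, first_n: int) -> "TinyTransformerEncoder":
        """Freeze the embedding tables and the first ``first_n`` blocks.

        The token and position embedding tables are always excluded from
        gradient updates (the fine-tuning convention for pretrained
        encoders); ``first_n`` counts transformer blocks. Freezing every
        block also freezes the final layer norm, so only post-encoder
        parameters can update.
        """
        if first_n < 0 or first_n > self.layer_count:
            raise DomainError(f"cannot freeze {first_n} of "
                              f"{self.layer_count} layers")
        self.tok_embed.requires_grad = False
        self.pos_embed.requires_grad = False
        for block in self.blocks[:first_n]:
            for p in block.parameters():
                p.requires_grad = False
        if first_n == self.layer_count:
            for p in self.ln_final.parameters():
                p.requires_grad = False
        return self

    def unfreeze(self) -> "TinyTransformerEncoder":
        for p in self.parameters():
            p.requires_grad = True
        return self

    def embed(self, ids: np.ndarray, attention_mask: np.ndarray) -> Tensor:
        """Per-token embeddings [B, T, d_model] for id matrix [B, T].

        Only attention-1 tokens act as keys, so masked (structural, special,
        padding) tokens never influence the returned heavy-atom embeddings.
        """
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
            attention_mask = np.asarray(attention_mask)[None, :]
        T = ids.shape[1]
        x = self.tok_embed[ids] + self.pos_embed[np.arange(T)]
        for block in self.blocks:
            x = block(x, attention_mask)
        return self.ln_final(x)

    __call__ = embed


class TableEncoder(Module):
    """Externally produced per-token embedding table behind the encoder
    interface (no transformer blocks; ``layer_count`` is 0)."""

    def __init__(self, embedding_matrix: np.ndarray, trainable: bool = False):
        super().__init__()
        self.table = Parameter(np.asarray(embedding_matrix))
        self.table.requires_grad = trainable

    @property
    def layer_count(self) -> int:
        return 0

    @property
    def d_out(self) -> int:
        return int(self.table.shape[1])

    def freeze(self, first_n: int) -> "TableEncoder":
        if first_n not in (0,):
            raise DomainError("TableEncoder has no transformer layers")
        self.table.requires_grad = False
        return self

    def embed(self, ids: np.ndarray, attention_mask: np.ndarray) -> Tensor:
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        return self.table[ids]

    __call__ = embed
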