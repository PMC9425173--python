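"""Question and sentence encoders.

Both encoders share one token-embedding table. The question encoder adds a
fixed sinusoidal positional encoding and runs a transformer stack; its
fixed-length summary vector is the sum of valid token states normalized by
question length. The sentence encoder processes sentences one by one (token
positions restart at 0 in each sentence) and adds a learned sentence-position
embedding indicating sentence order; its output is the per-token hidden
state grid for the whole document.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .config import ModelConfig
from .nn import Embedding, Module, TransformerEncoder, sinusoidal_encoding


@dataclass
class QuestionEncoding:
    hidden: Tensor        # [B, m, d] per-token states H_q
    vector: Tensor        # [B, d]  v_q = masked-sum(H_q) / m
    mask: np.ndarray      # [B, m]


@dataclass
class DocumentEncoding:
    hidden: Tensor            # [B, L, n, d] per-token states H_s
    token_mask: np.ndarray    # [B, L, n]
    sentence_mask: np.ndarray  # [B, L]

    @property
    def flat_hidden(self) -> Tensor:
        b, l_s, n_s, d = self.hidden.shape
        return self.hidden.reshape(b, l_s * n_s, d)

    @property
    def flat_token_mask(self) -> np.ndarray:
        b = self.token_mask.shape[0]
        return self.token_mask.reshape(b, -1)


def embed_question(ids: np.ndarray, embedding: Embedding) -> Tensor:
    """Token embedding plus sinusoidal position encoding (0-based)."""
    b, m = ids.shape
    pe = sinusoidal_encoding(m, embedding.weight.shape[1])
    return embedding(ids) + pe[None, :, :]


class QuestionEncoder(Module):
    def __init__(self, embedding: Embedding, config: ModelConfig, rng: np.random.Generator,
                 encoder: TransformerEncoder | None = None):
        super().__init__()
        self.embedding = embedding
        self.encoder = encoder or TransformerEncoder(
            config.n_enc_layers, config.d_model, config.ffn_dim, config.n_heads,
            rng, config.dropout,
        )

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> QuestionEncoding:
        x = embed_question(ids, self.embedding)
        hidden = self.encoder(x, mask)
        lengths = np.maximum(mask.sum(axis=-1, keepdims=True), 1).astype(np.float64)
        vector = hidden.mask(mask[:, :, None]).sum(axis=1) / lengths
        return QuestionEncoding(hidden, vector, np.asarray(mask, dtype=bool))


class SentenceEncoder(Module):
    """Shared transformer applied per sentence, with sentence-order embedding."""

    def __init__(self, embedding: Embedding, config: ModelConfig, rng: np.random.Generator,
                 encoder: TransformerEncoder | None = None):
        super().__init__()
        self.embedding = embedding
        self.sentence_pos = Embedding(config.max_sents, config.d_model, rng)
        self.encoder = encoder or TransformerEncoder(
            config.n_enc_layers, config.d_model, config.ffn_dim, config.n_heads,
            rng, config.dropout,
        )
        self.max_sents = config.max_sents

    def input_embeddings(self, sentence_ids: np.ndarray) -> Tensor:
        """Token embedding + within-sentence position + sentence-order embedding."""
        b, l_s, n_s = sentence_ids.shape
        d = self.embedding.weight.shape[1]
        pe = sinusoidal_encoding(n_s, d)                      # resets per sentence
        ranks = np.broadcast_to(np.arange(l_s), (b, l_s))
        spe = self.sentence_pos(ranks)                        # [B, L, d]
        return self.embedding(sentence_ids) + pe[None, None, :, :] + spe.reshape(b, l_s, 1, d)

    def __call__(self, sentence_ids: np.ndarray, token_mask: np.ndarray) -> DocumentEncoding:
        b, l_s, n_s = sentence_ids.shape
        if l_s > self.max_sents:
            raise ValueError(
                f"{l_s} sentences exceed max_sents={self.max_sents}; truncate upstream"
            )
        d = self.embedding.weight.shape[1]
        x = self.input_embeddings(sentence_ids)
        flat = x.reshape(b * l_s, n_s, d)
        flat_mask = token_mask.reshape(b * l_s, n_s)
        hidden = self.encoder(flat, flat_mask).reshape(b, l_s, n_s, d)
        sentence_mask = np.asarray(token_mask, dtype=bool).any(axis=-1)
        return DocumentEncoding(hidden, np.asarray(token_mask, dtype=bool), sentence_mask)
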