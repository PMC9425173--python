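"""Autoregressive decoder with the overall-integration mechanism.

Summary token embeddings are first fused with the question-document vector
through a sigmoid *integration gate* (a learned convex combination of the
two streams). Each decoder layer then runs causal self-attention + FFN over
the summary stream (the correlative summary s_y), cross-attends to the
question states and to the fused document states (s_q, s_s), and integrates
the three via two pairwise gate applications: (s_q with s_s), then with s_y.
The final layer's cross-attention weights feed the pointer views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .config import ModelConfig
from .encoder import QuestionEncoding
from .nn import (
    Embedding,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    sinusoidal_encoding,
)
from .two_step_attention import CoattentionResult, FusedDocument


@dataclass
class DecoderState:
    output: Tensor        # [B, T, d] predicted representations o_y
    beta_q_heads: Tensor  # [B, h, T, m] final-layer decoder->question weights
    beta_s_heads: Tensor  # [B, h, T, N_s] final-layer decoder->document weights


class IntegrationGate(Module):
    """fused = z * a + (1 - z) * b with z = sigmoid(W [a; b] + bias).

    When the overall-integration ablation is active the gate degenerates to
    the plain sum of the two streams.
    """

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(2 * d, d, rng)

    def __call__(self, a: Tensor, b: Tensor, ablated: bool = False) -> Tensor:
        if ablated:
            return a + b
        z = self.proj(concat([a, b], axis=-1)).sigmoid()
        return z * a + (1.0 - z) * b


class _CrossBlock(Module):
    """Cross-attention to question and document plus the pairwise gates."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.attn_q = MultiHeadAttention(d, config.n_heads, rng, config.dropout)
        self.attn_s = MultiHeadAttention(d, config.n_heads, rng, config.dropout)
        self.gate_qs = IntegrationGate(d, rng)
        self.gate_y = IntegrationGate(d, rng)

    def __call__(self, s_y: Tensor, question: QuestionEncoding, doc_hidden: Tensor,
                 doc_mask: np.ndarray, ablated: bool) -> tuple[Tensor, Tensor, Tensor]:
        s_q, beta_q = self.attn_q(s_y, question.hidden, question.mask)
        s_s, beta_s = self.attn_s(s_y, doc_hidden, doc_mask)
        fused_qs = self.gate_qs(s_q, s_s, ablated)
        o_y = self.gate_y(fused_qs, s_y, ablated)
        return o_y, beta_q, beta_s


class DecoderLayer(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator, with_cross: bool):
        super().__init__()
        d = config.d_model
        self.self_attn = MultiHeadAttention(d, config.n_heads, rng, config.dropout)
        self.ffn = FeedForward(d, config.ffn_dim, rng, config.dropout)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.cross = _CrossBlock(config, rng) if with_cross else None

    def __call__(self, x: Tensor, summary_mask: np.ndarray, question: QuestionEncoding,
                 doc_hidden: Tensor, doc_mask: np.ndarray, ablated: bool):
        attn_out, _ = self.self_attn(x, x, summary_mask, causal=True)
        s_y = self.ln1(x + attn_out)
        s_y = self.ln2(s_y + self.ffn(s_y))
        if self.cross is None:
            return s_y, None, None
        return self.cross(s_y, question, doc_hidden, doc_mask, ablated)


class IntegrationDecoder(Module):
    """Stack of decoder layers over gate-fused summary inputs.

    ``config.cross_attn`` selects whether cross-attention + gating run inside
    every layer (default) or once after the self-attention stack.
    """

    def __init__(self, embedding: Embedding, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.embedding = embedding
        self.config = config
        per_layer = config.cross_attn == "per-layer"
        self.context_gate = IntegrationGate(config.d_model, rng)
        self.layers = [
            DecoderLayer(config, rng, with_cross=per_layer)
            for _ in range(config.n_dec_layers)
        ]
        self.final_cross = None if per_layer else _CrossBlock(config, rng)

    def __call__(self, summary_in: np.ndarray, summary_mask: np.ndarray,
                 question: QuestionEncoding, doc: FusedDocument,
                 co: CoattentionResult) -> DecoderState:
        if summary_in.shape[1] == 0:
            raise ValueError("decoder needs a non-empty prefix (at least bos)")
        ablated = not self.config.overall_integration
        b, t = summary_in.shape
        d = self.embedding.weight.shape[1]
        pe = sinusoidal_encoding(t, d)
        x = self.embedding(summary_in) + pe[None, :, :]
        context = co.fused.reshape(b, 1, d) + Tensor(np.zeros((b, t, d)))  # broadcast
        x = self.context_gate(x, context, ablated)
        doc_hidden = doc.flat_hidden
        doc_mask = doc.flat_token_mask
        beta_q = beta_s = None
        for layer in self.layers:
            x, bq, bs = layer(x, summary_mask, question, doc_hidden, doc_mask, ablated)
            if bq is not None:
                beta_q, beta_s = bq, bs
        if self.final_cross is not None:
            x, beta_q, beta_s = self.final_cross(
                x, question, doc_hidden, doc_mask, ablated
            )
        return DecoderState(x, beta_q, beta_s)
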