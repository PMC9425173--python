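"""Two-step attention: intersentence attention, then coattention.

Step 1 condenses each sentence into per-head pooled vectors (multi-head
pooling), lets sentences attend to each other (scaled dot-product
self-attention over the pooled vectors), and fuses the resulting per-sentence
context back into every token state of that sentence through a gelu MLP with
a residual and layer norm. After this step each token representation carries
information from the other sentences.

Step 2 (coattention) scores each fused sentence against the question vector
with additive attention, yielding a relevance distribution over sentences
(alpha, reused later as the pointer's global document distribution) and a
fused question-document vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, masked_softmax
from .config import ModelConfig
from .nn import (
    GeluMLP,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    masked_mean,
)
from .encoder import DocumentEncoding


@dataclass
class SentenceHeads:
    probs: Tensor    # [B, h, L, n] within-sentence pooling distributions
    values: Tensor   # [B, h, L, n, d_head] value vectors
    summed: Tensor   # [B, h, L, d_head] weighted sums (pre-linear)
    pooled: Tensor   # [B, L, d] per-head linear + layer-norm, heads concatenated


@dataclass
class FusedDocument:
    hidden: Tensor            # [B, L, n, d] fused token states H_s'
    token_mask: np.ndarray
    sentence_mask: np.ndarray
    sentence_vectors: Tensor  # [B, L, d] masked means of fused token states

    @property
    def flat_hidden(self) -> Tensor:
        b, l_s, n_s, d = self.hidden.shape
        return self.hidden.reshape(b, l_s * n_s, d)

    @property
    def flat_token_mask(self) -> np.ndarray:
        return self.token_mask.reshape(self.token_mask.shape[0], -1)


@dataclass
class CoattentionResult:
    alpha: Tensor | np.ndarray  # [B, L] sentence relevance distribution
    fused: Tensor               # [B, d] question-document vector


class MultiHeadPooling(Module):
    """Learned weighted pooling of token states into per-head sentence vectors.

    Per head: a scalar logit per token, masked softmax within the sentence,
    weighted sum of value vectors, then a per-head linear map and layer norm.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d, h, dk = config.d_model, config.n_heads, config.d_head
        self.h, self.dk = h, dk
        self.score = Linear(d, h, rng)        # one logit per head
        self.value = Linear(d, d, rng)        # split into heads
        bound = np.sqrt(6.0 / (2 * dk))
        self.proj_w = Tensor(rng.uniform(-bound, bound, size=(h, dk, dk)), requires_grad=True)
        self.proj_b = Tensor(np.zeros((h, 1, dk)), requires_grad=True)
        self.ln = LayerNorm(dk)

    def __call__(self, doc: DocumentEncoding) -> SentenceHeads:
        b, l_s, n_s, d = doc.hidden.shape
        logits = self.score(doc.hidden)                       # [B, L, n, h]
        logits = logits.transpose(0, 3, 1, 2)                 # [B, h, L, n]
        probs = masked_softmax(logits, doc.token_mask[:, None, :, :], axis=-1)
        values = (
            self.value(doc.hidden)
            .reshape(b, l_s, n_s, self.h, self.dk)
            .transpose(0, 3, 1, 2, 4)                         # [B, h, L, n, dk]
        )
        summed = (probs.reshape(b, self.h, l_s, 1, n_s) @ values).reshape(
            b, self.h, l_s, self.dk
        )
        projected = summed @ self.proj_w + self.proj_b        # per-head linear
        pooled = self.ln(projected).transpose(0, 2, 1, 3).reshape(b, l_s, d)
        return SentenceHeads(probs, values, summed, pooled)


class IntersentenceAttention(Module):
    """Scaled dot-product self-attention across pooled sentence vectors."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(config.d_model, config.n_heads, rng, config.dropout)

    def __call__(self, pooled: Tensor, sentence_mask: np.ndarray) -> Tensor:
        context, _ = self.attn(pooled, pooled, sentence_mask)
        return context  # [B, L, d]


class TokenFusion(Module):
    """Add each sentence's context vector to its tokens; gelu MLP + residual + LN."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.mlp = GeluMLP(config.d_model, config.ffn_dim, config.d_model, rng)
        self.ln = LayerNorm(config.d_model)

    def __call__(self, hidden: Tensor, context: Tensor) -> Tensor:
        b, l_s, n_s, d = hidden.shape
        u = hidden + context.reshape(b, l_s, 1, d)
        return self.ln(u + self.mlp(u))


class Coattention(Module):
    """Additive attention of the question vector over sentence vectors."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.w_sent = Linear(d, d, rng, bias=False)
        self.w_query = Linear(d, d, rng, bias=False)
        self.v = Linear(d, 1, rng, bias=False)
        self.mlp = GeluMLP(2 * d, config.ffn_dim, d, rng)

    def __call__(self, question_vector: Tensor, sentence_vectors: Tensor,
                 sentence_mask: np.ndarray) -> CoattentionResult:
        b, l_s, d = sentence_vectors.shape
        scores = self.v(
            (self.w_sent(sentence_vectors) + self.w_query(question_vector).reshape(b, 1, d)).tanh()
        ).reshape(b, l_s)
        alpha = masked_softmax(scores, sentence_mask, axis=-1)
        mix = (alpha.reshape(b, 1, l_s) @ sentence_vectors).reshape(b, d)
        fused = self.mlp(concat([question_vector, mix], axis=-1))
        return CoattentionResult(alpha, fused)


class TwoStepAttention(Module):
    """Full step-1 + step-2 pipeline with the ablation bypasses.

    With ``intersentence`` off the token states pass through unchanged; with
    ``coattention`` off alpha becomes uniform over valid sentences and the
    fused vector falls back to the question vector.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.pooling = MultiHeadPooling(config, rng)
        self.intersentence = IntersentenceAttention(config, rng)
        self.fusion = TokenFusion(config, rng)
        self.coattention = Coattention(config, rng)

    def __call__(self, doc: DocumentEncoding, question_vector: Tensor
                 ) -> tuple[FusedDocument, CoattentionResult]:
        if self.config.intersentence:
            heads = self.pooling(doc)
            context = self.intersentence(heads.pooled, doc.sentence_mask)
            fused_tokens = self.fusion(doc.hidden, context)
        else:
            fused_tokens = doc.hidden
        sentence_vectors = masked_mean(fused_tokens, doc.token_mask, axis=2)
        fused_doc = FusedDocument(
            fused_tokens, doc.token_mask, doc.sentence_mask, sentence_vectors
        )
        if self.config.coattention:
            co = self.coattention(question_vector, sentence_vectors, doc.sentence_mask)
        else:
            counts = np.maximum(doc.sentence_mask.sum(axis=-1, keepdims=True), 1)
            alpha = np.where(doc.sentence_mask, 1.0 / counts, 0.0)
            co = CoattentionResult(alpha, question_vector)
        return fused_doc, co
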