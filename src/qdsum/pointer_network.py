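"""Multi-view pointer network.

The next-token distribution mixes three views:

* a vocabulary softmax over the fixed vocabulary, with weights tied to the
  shared token-embedding table;
* a question-copy distribution: head-averaged final-layer decoder-to-question
  attention, scatter-added over the extended ids of the question tokens;
* a document-copy distribution: the coattention sentence distribution acts
  as a global factor over each token's head-averaged local attention weight,
  scatter-added over the extended ids of the document tokens.

A learned 3-way softmax gate over the predicted representation yields the
mixture weights; the final distribution lives on the extended vocabulary
(fixed vocabulary + per-example OOV slots), so out-of-vocabulary source
tokens are reachable only through the copy views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather_last, masked_softmax, scatter_sum
from .config import ModelConfig
from .nn import Linear, Module

_EPS = 1e-12


@dataclass
class StepDistribution:
    p_vocab: Tensor       # [B, T, V]
    p_question: Tensor    # [B, T, V + n_oov]
    p_document: Tensor    # [B, T, V + n_oov]
    mixture: Tensor       # [B, T, 3] weights (lambda_v, lambda_q, lambda_s)
    final: Tensor         # [B, T, V + n_oov]


def _renormalize(scattered: Tensor) -> Tensor:
    denom = scattered.sum(axis=-1, keepdims=True).clip_min(_EPS)
    return scattered / denom


def question_copy_distribution(beta_q_heads: Tensor, question_ids_extended: np.ndarray,
                               extended_size: int) -> Tensor:
    """Head-averaged attention mass scatter-added onto question token ids."""
    beta = beta_q_heads.mean(axis=1)                      # [B, T, m]
    ids = question_ids_extended[:, None, :]               # broadcast over T
    return _renormalize(scatter_sum(beta, ids, extended_size))


def document_copy_distribution(beta_s_heads: Tensor, alpha, document_ids_extended: np.ndarray,
                               extended_size: int) -> Tensor:
    """Global (sentence) x local (token) attention, scattered onto document ids.

    ``alpha`` is the coattention distribution over the L sentences (uniform
    ndarray when coattention is ablated, in which case this reduces to the
    local attention); ``document_ids_extended`` is [B, L, n].
    """
    b, l_s, n_s = document_ids_extended.shape
    beta = beta_s_heads.mean(axis=1)                      # [B, T, N_s]
    sent_index = np.repeat(np.arange(l_s), n_s)[None, :]  # [1, N_s]
    if isinstance(alpha, Tensor):
        token_alpha = gather_last(alpha, np.broadcast_to(sent_index, (b, l_s * n_s)))
        weights = beta * token_alpha.reshape(b, 1, l_s * n_s)
    else:
        token_alpha = np.take_along_axis(
            np.asarray(alpha), np.broadcast_to(sent_index, (b, l_s * n_s)), axis=-1
        )
        weights = beta * token_alpha[:, None, :]
    ids = document_ids_extended.reshape(b, 1, l_s * n_s)
    return _renormalize(scatter_sum(weights, ids, extended_size))


def vocab_distribution(output: Tensor, embedding_table: Tensor) -> Tensor:
    """Softmax over the fixed vocabulary with tied embedding weights."""
    logits = output @ embedding_table.transpose(1, 0)
    return masked_softmax(logits, np.ones(logits.shape, dtype=bool), axis=-1)


class PointerNetwork(Module):
    """3-way mixture gate over vocabulary, question-copy, document-copy views."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.gate = Linear(config.d_model, 3, rng)

    def __call__(self, output: Tensor, beta_q_heads: Tensor, beta_s_heads: Tensor,
                 alpha, question_ids_extended: np.ndarray,
                 document_ids_extended: np.ndarray, embedding_table: Tensor,
                 n_oov: int) -> StepDistribution:
        b, t, _ = output.shape
        vocab = embedding_table.shape[0]
        extended = vocab + n_oov
        p_v = vocab_distribution(output, embedding_table)
        if not self.config.multiview_pointer:
            final = _pad_to_extended(p_v, n_oov)
            lam = Tensor(np.tile([1.0, 0.0, 0.0], (b, t, 1)))
            zero = Tensor(np.zeros((b, t, extended)))
            return StepDistribution(p_v, zero, zero, lam, final)
        p_q = question_copy_distribution(beta_q_heads, question_ids_extended, extended)
        p_s = document_copy_distribution(
            beta_s_heads, alpha, document_ids_extended, extended
        )
        lam = masked_softmax(self.gate(output), np.ones((b, t, 3), dtype=bool), axis=-1)
        final = (
            lam[:, :, 0:1] * _pad_to_extended(p_v, n_oov)
            + lam[:, :, 1:2] * p_q
            + lam[:, :, 2:3] * p_s
        )
        return StepDistribution(p_v, p_q, p_s, lam, final)


def _pad_to_extended(p_v: Tensor, n_oov: int) -> Tensor:
    if n_oov == 0:
        return p_v
    return concat([p_v, Tensor(np.zeros(p_v.shape[:-1] + (n_oov,)))], axis=-1)


def mix_distributions(output_t: Tensor, p_v: Tensor, p_q: Tensor, p_s: Tensor,
                      gate: Linear) -> tuple[Tensor, Tensor]:
    """Single-step mixture (used directly in unit tests): returns (P, lambda)."""
    lam = masked_softmax(gate(output_t), np.ones(output_t.shape[:-1] + (3,), dtype=bool))
    n_oov = p_q.shape[-1] - p_v.shape[-1]
    final = (
        lam[..., 0:1] * _pad_to_extended(p_v, n_oov)
        + lam[..., 1:2] * p_q
        + lam[..., 2:3] * p_s
    )
    return final, lam
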