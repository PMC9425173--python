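"""End-to-end summarization model: encoders, two-step attention,
integration decoder, and multi-view pointer wired together."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import ModelConfig
from .corpus import Batch, Vocabulary
from .encoder import QuestionEncoder, SentenceEncoder
from .integration_decoder import IntegrationDecoder
from .nn import Embedding, Module, TransformerEncoder, bind_dropout_rng
from .pointer_network import PointerNetwork, StepDistribution
from .two_step_attention import CoattentionResult, FusedDocument, TwoStepAttention


class Summarizer(Module):
    """Question-driven abstractive summarizer.

    One shared token-embedding table serves the question encoder, the
    sentence encoder, the decoder, and (tied) the vocabulary softmax of the
    pointer network. The two encoders have separate transformer weights
    unless ``config.share_encoders``.
    """

    def __init__(self, vocab_size: int, config: ModelConfig, seed: int = 13):
        super().__init__()
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        self.embedding = Embedding(vocab_size, config.d_model, rng)
        shared = (
            TransformerEncoder(
                config.n_enc_layers, config.d_model, config.ffn_dim,
                config.n_heads, rng, config.dropout,
            )
            if config.share_encoders
            else None
        )
        self.question_encoder = QuestionEncoder(self.embedding, config, rng, shared)
        self.sentence_encoder = SentenceEncoder(self.embedding, config, rng, shared)
        self.two_step = TwoStepAttention(config, rng)
        self.decoder = IntegrationDecoder(self.embedding, config, rng)
        self.pointer = PointerNetwork(config, rng)
        self.eval()  # training loop switches to train mode and binds dropout

    def bind_rng(self, rng: np.random.Generator) -> None:
        bind_dropout_rng(self, rng)

    def encode(self, batch: Batch) -> tuple:
        """Run encoders + two-step attention once for a batch."""
        question = self.question_encoder(batch.question, batch.question_mask)
        doc = self.sentence_encoder(batch.sentences, batch.token_mask)
        fused_doc, co = self.two_step(doc, question.vector)
        return question, fused_doc, co

    def forward(self, batch: Batch, encoded: tuple | None = None) -> StepDistribution:
        """Teacher-forced distributions over the extended vocabulary, [B,T,V+n_oov]."""
        question, fused_doc, co = encoded if encoded is not None else self.encode(batch)
        state = self.decoder(
            batch.summary_in, batch.summary_mask, question, fused_doc, co
        )
        return self.pointer(
            state.output, state.beta_q_heads, state.beta_s_heads, co.alpha,
            batch.question_ext, batch.sentences_ext, self.embedding.weight,
            batch.n_oov,
        )

    __call__ = forward

    def step_distribution(self, batch: Batch, encoded: tuple) -> np.ndarray:
        """Final-position next-token probabilities (decoding helper), [B, V+n_oov]."""
        dist = self.forward(batch, encoded)
        return dist.final.data[:, -1, :]

    @staticmethod
    def replicate_encoded(encoded: tuple, k: int) -> tuple:
        """Repeat single-example encoder outputs across k hypotheses."""
        from .autodiff import Tensor
        from .encoder import QuestionEncoding

        question, doc, co = encoded
        rep_t = lambda t: Tensor(np.repeat(t.data, k, axis=0))
        rep = lambda a: np.repeat(a, k, axis=0)
        q = QuestionEncoding(rep_t(question.hidden), rep_t(question.vector), rep(question.mask))
        d = FusedDocument(rep_t(doc.hidden), rep(doc.token_mask), rep(doc.sentence_mask),
                          rep_t(doc.sentence_vectors))
        alpha = co.alpha
        alpha = rep_t(alpha) if isinstance(alpha, Tensor) else rep(np.asarray(alpha))
        return q, d, CoattentionResult(alpha, rep_t(co.fused))

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_model(vocab: Vocabulary, config: ModelConfig, seed: int = 13) -> Summarizer:
    return Summarizer(len(vocab), config, seed)
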