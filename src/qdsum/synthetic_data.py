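"""Synthetic corpora with the statistical shape of PubMedQA.

The generator emulates the aggregate statistics of the real data — question
length ~16.3 words, ~9.32 sentences per document, ~238 document words,
~41-word summaries, a 92.8/7.2 yes/no label split — over an abstract token
inventory, with two controllable knobs the copy mechanism cares about:

``copy_rate``
    fraction of summary tokens drawn verbatim from the source. Copied tokens
    are planted in exactly one *answer-bearing* sentence (uniformly placed),
    which also repeats a few question tokens, so question-document
    coattention has a learnable signal.
``oov_rate``
    fraction of source content tokens outside the model vocabulary. Such
    tokens can only reach the summary through the pointer views.

Non-copied summary tokens come from a generator-only pool that never appears
in documents, so novel-n-gram proportions are exact functions of
``copy_rate`` at the boundaries.

Lengths are Poisson around the configured means (clipped to >= 1); the data
are abstract tokens, not biomedical text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import SPECIAL_TOKENS, RawExample, Vocabulary

NEGATION_CUE = "neg"  # presence in the answer-bearing sentence <=> label "no"


@dataclass
class SynthConfig:
    """Generator parameters; defaults follow the real-corpus statistics."""

    vocab_size: int = 500           # total model vocabulary incl. specials
    n_examples: int = 1000
    mean_question_len: float = 16.3
    mean_summary_len: float = 41.0
    mean_n_sentences: float = 9.32
    mean_doc_len: float = 238.0
    copy_rate: float = 0.72         # ~matches the 27.8% novel-unigram rate of references
    oov_rate: float = 0.1
    yes_fraction: float = 0.928
    seed: int = 13

    def __post_init__(self):
        for name in ("copy_rate", "oov_rate", "yes_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("mean_question_len", "mean_summary_len", "mean_n_sentences", "mean_doc_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vocab_size < len(SPECIAL_TOKENS) + 3:
            raise ValueError(
                f"vocab_size must exceed the {len(SPECIAL_TOKENS)} special tokens "
                "plus the cue and content pools"
            )

    @property
    def n_novel(self) -> int:
        """Size of the generator-only pool used for non-copied summary tokens."""
        usable = self.vocab_size - len(SPECIAL_TOKENS) - 1  # minus cue token
        return max(1, min(200, usable // 4))

    @property
    def n_content(self) -> int:
        """Size of the in-vocabulary content-word pool."""
        return self.vocab_size - len(SPECIAL_TOKENS) - 1 - self.n_novel

    @property
    def n_oov_pool(self) -> int:
        """Size of the out-of-vocabulary surface pool."""
        return max(50, self.n_content // 2)


def _pools(config: SynthConfig) -> tuple[list[str], list[str], list[str]]:
    content = [f"w{i:04d}" for i in range(config.n_content)]
    novel = [f"z{i:04d}" for i in range(config.n_novel)]
    oov = [f"x{i:04d}" for i in range(config.n_oov_pool)]
    return content, novel, oov


def model_vocabulary(config: SynthConfig) -> Vocabulary:
    """The word-level model vocabulary matching ``config.vocab_size``.

    Contains the content and novel pools and the negation cue; the OOV pool
    is deliberately absent so its tokens exercise the extended vocabulary.
    """
    content, novel, _ = _pools(config)
    return Vocabulary.from_tokens(content + novel + [NEGATION_CUE])


def _poisson_len(rng: np.random.Generator, mean: float) -> int:
    return max(1, int(rng.poisson(mean)))


def _source_token(rng: np.random.Generator, config: SynthConfig,
                  content: list[str], oov: list[str]) -> str:
    pool = oov if rng.random() < config.oov_rate else content
    return pool[rng.integers(len(pool))]


def generate_corpus(config: SynthConfig) -> list[RawExample]:
    """Generate ``config.n_examples`` raw (question, sentences, summary, label)
    instances, deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    content, novel, oov = _pools(config)
    out: list[RawExample] = []
    for _ in range(config.n_examples):
        # question: a few topic tokens (shared with the answer sentence) + filler
        m = _poisson_len(rng, config.mean_question_len)
        n_topic = min(3, m)
        topic = [content[rng.integers(len(content))] for _ in range(n_topic)]
        question = topic + [content[rng.integers(len(content))] for _ in range(m - n_topic)]

        # summary: copied tokens (possibly OOV) vs novel-pool tokens
        n = _poisson_len(rng, config.mean_summary_len)
        copied_flags = rng.random(n) < config.copy_rate
        summary: list[str] = []
        copied_tokens: list[str] = []
        for flag in copied_flags:
            if flag:
                tok = _source_token(rng, config, content, oov)
                copied_tokens.append(tok)
                summary.append(tok)
            else:
                summary.append(novel[rng.integers(len(novel))])

        # document: l_s sentences, one answer-bearing sentence carrying the
        # copied tokens and the topic tokens (and the negation cue iff "no")
        l_s = _poisson_len(rng, config.mean_n_sentences)
        doc_len = max(l_s, int(rng.poisson(config.mean_doc_len)))
        lengths = rng.multinomial(doc_len - l_s, np.full(l_s, 1.0 / l_s)) + 1
        answer_idx = int(rng.integers(l_s))
        label = "yes" if rng.random() < config.yes_fraction else "no"
        sentences: list[str] = []
        for i, length in enumerate(lengths):
            if i == answer_idx:
                body = list(topic) + copied_tokens
                if label == "no":
                    body.insert(0, NEGATION_CUE)
                while len(body) < length:
                    body.append(_source_token(rng, config, content, oov))
            else:
                body = [
                    _source_token(rng, config, content, oov) for _ in range(length)
                ]
            sentences.append(" ".join(body))
        out.append(RawExample(" ".join(question), sentences, " ".join(summary), label))
    return out


def generate_qa_pairs(config: SynthConfig) -> list[tuple[str, str, str]]:
    """(question, text, label) triples whose label is a deterministic function
    of the negation cue in the text, with yes_fraction marginal labels."""
    rng = np.random.default_rng(config.seed)
    content, _, _ = _pools(config)
    pairs: list[tuple[str, str, str]] = []
    for _ in range(config.n_examples):
        m = _poisson_len(rng, config.mean_question_len)
        question = " ".join(content[rng.integers(len(content))] for _ in range(m))
        k = _poisson_len(rng, config.mean_summary_len)
        body = [content[rng.integers(len(content))] for _ in range(k)]
        label = "yes" if rng.random() < config.yes_fraction else "no"
        if label == "no":
            body.insert(int(rng.integers(len(body) + 1)), NEGATION_CUE)
        pairs.append((question, " ".join(body), label))
    return pairs
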