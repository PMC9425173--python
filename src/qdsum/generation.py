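"""Beam-search decoding with n-gram blocking.

Hypotheses live on the extended vocabulary, so copied out-of-vocabulary
source tokens can appear in the output; they map back to ``<unk>`` when fed
to the decoder embeddings and resolve to their source surface forms at
detokenization. Within a hypothesis any continuation that would recreate an
n-gram already present is forbidden (probability zero), the standard
repeat-blocking rule. Hypotheses are ranked by cumulative log probability
during search and by length-normalized score at selection; score ties break
toward the lower token id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus import BOS, EOS, PAD, UNK, Batch, Example, Vocabulary, make_batch
from .model import Summarizer

logger = logging.getLogger(__name__)

NEG_INF = -np.inf


@dataclass
class Hypothesis:
    ids: list[int] = field(default_factory=list)  # generated tokens (no bos)
    logprob: float = 0.0
    finished: bool = False

    def score(self, length_norm: bool = True) -> float:
        if not length_norm:
            return self.logprob
        return self.logprob / max(len(self.ids), 1)


def _blocked_tokens(ids: list[int], n: int) -> set[int]:
    """Token ids that would complete an n-gram already present in ``ids``."""
    if n <= 0 or len(ids) < n - 1:
        return set()
    prefix = tuple(ids[-(n - 1) :]) if n > 1 else ()
    blocked = set()
    for i in range(len(ids) - n + 1):
        if tuple(ids[i : i + n - 1]) == prefix:
            blocked.add(ids[i + n - 1])
    return blocked


def _prefix_batch(batch: Batch, prefixes: list[list[int]], vocab_size: int) -> Batch:
    """Replicate a single-example batch across hypotheses with given prefixes."""
    k = len(prefixes)
    t = max(len(p) for p in prefixes) + 1
    summary_in = np.zeros((k, t), dtype=np.int64)
    summary_mask = np.zeros((k, t), dtype=bool)
    summary_in[:, 0] = BOS
    for i, p in enumerate(prefixes):
        base = [tok if tok < vocab_size else UNK for tok in p]
        summary_in[i, 1 : 1 + len(base)] = base
        summary_mask[i, : len(base) + 1] = True
    rep = lambda a: np.repeat(a, k, axis=0)
    return Batch(
        rep(batch.question), rep(batch.question_ext), rep(batch.question_mask),
        rep(batch.sentences), rep(batch.sentences_ext), rep(batch.token_mask),
        rep(batch.sentence_mask), summary_in, summary_in, summary_mask,
        batch.labels * k, batch.n_oov, batch.examples,
    )


def beam_search(model: Summarizer, example, vocab: Vocabulary, beam: int | None = None,
                block_ngram: int | None = None, max_len: int = 100,
                length_norm: bool = True) -> Hypothesis:
    """Length-bucketed beam search over the extended vocabulary.

    ``example`` is a RawExample, Example, or single-example Batch. With
    ``beam=1`` this is greedy decoding (argmax per step with blocking).
    """
    config = model.config
    beam = config.beam if beam is None else beam
    block_ngram = config.block_ngram if block_ngram is None else block_ngram
    if beam < 1:
        raise ValueError("beam must be >= 1")
    batch = example if isinstance(example, Batch) else make_batch([example], vocab)
    model.eval()
    encoded = model.encode(batch)
    live = [Hypothesis()]
    finished: list[Hypothesis] = []
    for _ in range(max_len):
        probs = model.step_distribution(
            _prefix_batch(batch, [h.ids for h in live], model.vocab_size),
            model.replicate_encoded(encoded, len(live)),
        )
        with np.errstate(divide="ignore"):
            log_probs = np.log(probs)
        candidates: list[Hypothesis] = []
        for row, hyp in zip(log_probs, live):
            for tok in _blocked_tokens(hyp.ids, block_ngram):
                row[tok] = NEG_INF
            # top (2*beam) continuations so eos is never crowded out;
            # ties toward the lower token id
            order = np.lexsort((np.arange(row.size), -row))[: 2 * beam]
            for tok in order:
                if row[tok] == NEG_INF:
                    continue
                new = Hypothesis(hyp.ids + [int(tok)], hyp.logprob + float(row[tok]),
                                 finished=int(tok) == EOS)
                candidates.append(new)
        if not candidates:
            break
        candidates.sort(key=lambda h: (-h.logprob, h.ids[-1]))
        live = []
        for h in candidates:
            if h.finished:
                finished.append(h)
            elif len(live) < beam:
                live.append(h)
        if not live:
            break
        if finished:
            # sound stop: a live hypothesis's logprob only decreases, so its
            # best achievable score is bounded by logprob (raw scoring) or
            # logprob / max_len (length-normalized, logprob <= 0)
            best_finished = max(h.score(length_norm) for h in finished)
            horizon = max_len if length_norm else 1
            if max(h.logprob / horizon for h in live) <= best_finished:
                break
    if finished:
        return max(finished, key=lambda h: (h.score(length_norm), -h.ids[0] if h.ids else 0))
    logger.warning("max_len reached with no finished hypothesis")
    return max(live, key=lambda h: h.score(length_norm))


def greedy_decode(model: Summarizer, example, vocab: Vocabulary,
                  block_ngram: int | None = None, max_len: int = 100) -> Hypothesis:
    return beam_search(model, example, vocab, beam=1, block_ngram=block_ngram,
                       max_len=max_len)


def detokenize(hypothesis: Hypothesis, vocab: Vocabulary, oov_map: dict[str, int]) -> str:
    """Resolve extended ids through the example's oov_map; undo BPE."""
    inverse = {i: piece for piece, i in oov_map.items()}
    pieces = []
    for tok in hypothesis.ids:
        if tok in (PAD, BOS, EOS):
            continue
        if tok < len(vocab):
            pieces.append(vocab.id_to_token[tok])
        elif tok in inverse:
            pieces.append(inverse[tok])
        else:
            raise ValueError(f"extended id {tok} not present in this example's oov_map")
    if vocab.merges is None:
        return " ".join(pieces)
    from .corpus import EOW

    return "".join(pieces).replace(EOW, " ").strip()


def summarize(model: Summarizer, raw_or_example, vocab: Vocabulary, **kwargs) -> str:
    """Decode one instance and return the summary text."""
    from .corpus import make_example

    example = raw_or_example
    if not isinstance(example, Example):
        example = make_example(example, vocab)
    hyp = beam_search(model, example, vocab, **kwargs)
    return detokenize(hyp, vocab, example.oov_map)
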