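"""Text ingestion: BPE vocabulary, PubMedQA reading, batching.

The copy mechanism needs every source token to have an id even when it is
out of the fixed vocabulary, so each example carries an ``oov_map`` assigning
*extended* ids ``|V|, |V|+1, ...`` to source-only tokens (pointer-generator
convention, per-example scope). Base-id arrays replace those tokens with
``<unk>`` (embeddings only know the fixed vocabulary); extended-id arrays
keep them copyable.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

PAD, BOS, EOS, UNK, SEP = 0, 1, 2, 3, 4
SPECIAL_TOKENS = ["<pad>", "<bos>", "<eos>", "<unk>", "<sep>"]
EOW = "</w>"  # end-of-word marker carried by a word's last BPE symbol

_SENT_SPLIT = re.compile(r"(?<=[.?!])\s+")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitting on terminal punctuation + whitespace."""
    parts = [p.strip() for p in _SENT_SPLIT.split(text.strip())]
    return [p for p in parts if p]


class Vocabulary:
    """Subword inventory with special tokens; maps text <-> integer ids.

    Two modes share one interface: BPE (``train_bpe``) splits whitespace
    words into merge-derived subwords; word-level (``from_tokens``) treats
    each whitespace word as atomic, which the synthetic corpora use.
    """

    def __init__(self, id_to_token: list[str], merges: list[tuple[str, str]] | None):
        if id_to_token[: len(SPECIAL_TOKENS)] != SPECIAL_TOKENS:
            raise ValueError("vocabulary must start with the special tokens")
        self.id_to_token = list(id_to_token)
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}
        if len(self.token_to_id) != len(self.id_to_token):
            raise ValueError("duplicate tokens in vocabulary")
        self.merges = merges  # None => word-level mode
        self._merge_rank = (
            {pair: i for i, pair in enumerate(merges)} if merges is not None else {}
        )

    # -- construction -------------------------------------------------------

    @classmethod
    def train_bpe(cls, texts, num_merges: int) -> "Vocabulary":
        """Learn ``num_merges`` BPE merges from whitespace-tokenized texts.

        Deterministic: merge choice is by pair frequency, ties broken by the
        lexicographically smallest pair.
        """
        word_freq: Counter[str] = Counter()
        for text in texts:
            word_freq.update(text.split())
        if not word_freq:
            raise ValueError("empty corpus: no words to train BPE on")
        words = {w: _word_symbols(w) for w in word_freq}
        merges: list[tuple[str, str]] = []
        for _ in range(num_merges):
            pairs: Counter[tuple[str, str]] = Counter()
            for w, syms in words.items():
                f = word_freq[w]
                for a, b in zip(syms, syms[1:]):
                    pairs[(a, b)] += f
            if not pairs:
                break
            best = max(pairs.items(), key=lambda kv: (kv[1], _neg_lex(kv[0])))[0]
            merges.append(best)
            words = {w: _apply_merge(syms, best) for w, syms in words.items()}
        alphabet = sorted({s for w in word_freq for s in _word_symbols(w)})
        tokens = SPECIAL_TOKENS + alphabet + ["".join(p) for p in merges]
        # a merge can reproduce an existing token only if the corpus repeats
        # structure; dedupe while keeping first occurrence
        seen: set[str] = set()
        unique = [t for t in tokens if not (t in seen or seen.add(t))]
        return cls(unique, merges)

    @classmethod
    def from_tokens(cls, tokens) -> "Vocabulary":
        """Word-level vocabulary over an iterable of atomic word tokens."""
        extra = sorted(set(tokens) - set(SPECIAL_TOKENS))
        return cls(SPECIAL_TOKENS + extra, merges=None)

    # -- tokenization -------------------------------------------------------

    def tokenize(self, text: str) -> list[str]:
        """Text -> subword (or word) pieces; no id mapping yet."""
        if self.merges is None:
            return text.split()
        pieces: list[str] = []
        for word in text.split():
            pieces.extend(self._bpe_word(word))
        return pieces

    def _bpe_word(self, word: str) -> list[str]:
        syms = _word_symbols(word)
        while len(syms) > 1:
            ranked = [
                (self._merge_rank[p], p)
                for p in set(zip(syms, syms[1:]))
                if p in self._merge_rank
            ]
            if not ranked:
                break
            _, best = min(ranked)
            syms = _apply_merge(syms, best)
        return syms

    def encode(self, text: str) -> list[int]:
        return [self.token_to_id.get(p, UNK) for p in self.tokenize(text)]

    def decode(self, ids) -> str:
        pieces = []
        for i in ids:
            if i in (PAD, BOS, EOS):
                continue
            pieces.append(self.id_to_token[i])
        if self.merges is None:
            return " ".join(pieces)
        return "".join(pieces).replace(EOW, " ").strip()

    def piece_to_text(self, piece: str) -> str:
        """Surface form of one piece (strips the end-of-word marker)."""
        if self.merges is None:
            return piece
        return piece.replace(EOW, " ").strip()

    def __len__(self) -> int:
        return len(self.id_to_token)

    # -- serialization ------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "tokens.txt").write_text(
            "\n".join(self.id_to_token) + "\n", encoding="utf-8"
        )
        if self.merges is not None:
            lines = [f"{a}\t{b}" for a, b in self.merges]
            (directory / "merges.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, directory) -> "Vocabulary":
        directory = Path(directory)
        tokens = (directory / "tokens.txt").read_text(encoding="utf-8").splitlines()
        merges_path = directory / "merges.txt"
        merges = None
        if merges_path.exists():
            merges = [
                tuple(line.split("\t"))
                for line in merges_path.read_text(encoding="utf-8").splitlines()
                if line
            ]
        return cls(tokens, merges)


def _word_symbols(word: str) -> list[str]:
    syms = list(word)
    syms[-1] = syms[-1] + EOW
    return syms


def _apply_merge(syms: list[str], pair: tuple[str, str]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(syms):
        if i + 1 < len(syms) and (syms[i], syms[i + 1]) == pair:
            out.append(syms[i] + syms[i + 1])
            i += 2
        else:
            out.append(syms[i])
            i += 1
    return out


def _neg_lex(pair: tuple[str, str]):
    """Key making lexicographically smaller pairs sort as larger for max()."""
    return tuple(tuple(-ord(c) for c in s) for s in pair)


def build_vocabulary(texts, num_merges: int) -> Vocabulary:
    """BPE vocabulary from an iterable of texts; see Vocabulary.train_bpe."""
    return Vocabulary.train_bpe(texts, num_merges)


# -- examples ---------------------------------------------------------------


@dataclass
class RawExample:
    """One (question, sentences, summary, label) instance as raw text."""

    question: str
    sentences: list[str]
    summary: str
    label: str | None = None  # "yes" | "no" | None


@dataclass
class Example:
    """Token-id view of one instance, with extended ids for copyable OOVs."""

    question: list[int]
    question_ext: list[int]
    sentences: list[list[int]]
    sentences_ext: list[list[int]]
    summary: list[int]
    summary_ext: list[int]
    label: str | None
    oov_map: dict[str, int]  # source-only piece -> extended id >= |V|


@dataclass
class Limits:
    max_q: int = 60
    max_sent_len: int = 100
    max_sents: int = 20
    max_summary: int = 100


def make_example(raw: RawExample, vocab: Vocabulary, limits: Limits | None = None) -> Example:
    limits = limits or Limits()
    q_pieces = vocab.tokenize(raw.question)[: limits.max_q]
    sent_pieces = [
        vocab.tokenize(s)[: limits.max_sent_len] for s in raw.sentences[: limits.max_sents]
    ]
    sent_pieces = [p for p in sent_pieces if p]
    sum_pieces = vocab.tokenize(raw.summary)[: limits.max_summary]
    if not q_pieces or not sent_pieces:
        raise ValueError("example must have a non-empty question and at least one sentence")

    oov_map: dict[str, int] = {}

    def ext_id(piece: str, grow: bool) -> int:
        if piece in vocab.token_to_id:
            return vocab.token_to_id[piece]
        if piece not in oov_map:
            if not grow:
                return UNK
            oov_map[piece] = len(vocab) + len(oov_map)
        return oov_map[piece]

    base = lambda p: vocab.token_to_id.get(p, UNK)
    question = [base(p) for p in q_pieces]
    question_ext = [ext_id(p, grow=True) for p in q_pieces]
    sentences = [[base(p) for p in s] for s in sent_pieces]
    sentences_ext = [[ext_id(p, grow=True) for p in s] for s in sent_pieces]
    summary = [base(p) for p in sum_pieces]
    summary_ext = [ext_id(p, grow=False) for p in sum_pieces]
    return Example(
        question, question_ext, sentences, sentences_ext, summary, summary_ext,
        raw.label, oov_map,
    )


@dataclass
class Batch:
    """Padded, masked arrays for a list of examples (pad id 0 everywhere)."""

    question: np.ndarray          # [B, m] base ids
    question_ext: np.ndarray      # [B, m] extended ids
    question_mask: np.ndarray     # [B, m] bool
    sentences: np.ndarray         # [B, L, n] base ids
    sentences_ext: np.ndarray     # [B, L, n]
    token_mask: np.ndarray        # [B, L, n] bool
    sentence_mask: np.ndarray     # [B, L] bool
    summary_in: np.ndarray        # [B, T] bos + base summary ids
    summary_tgt: np.ndarray       # [B, T] extended summary ids + eos
    summary_mask: np.ndarray      # [B, T] bool (over targets)
    labels: list[str | None]
    n_oov: int                    # max per-example OOV count in the batch
    examples: list[Example] = field(repr=False, default_factory=list)

    @property
    def size(self) -> int:
        return self.question.shape[0]


def make_batch(examples, vocab: Vocabulary, limits: Limits | None = None) -> Batch:
    """Pad a list of (raw or encoded) examples into dense masked arrays."""
    if not examples:
        raise ValueError("cannot build a batch from zero examples")
    limits = limits or Limits()
    encoded = [
        ex if isinstance(ex, Example) else make_example(ex, vocab, limits) for ex in examples
    ]
    b = len(encoded)
    m = max(len(e.question) for e in encoded)
    l_s = max(len(e.sentences) for e in encoded)
    n_s = max(len(s) for e in encoded for s in e.sentences)
    t = max(len(e.summary) for e in encoded) + 1  # +1 for bos/eos shift

    question = np.zeros((b, m), dtype=np.int64)
    question_ext = np.zeros((b, m), dtype=np.int64)
    sentences = np.zeros((b, l_s, n_s), dtype=np.int64)
    sentences_ext = np.zeros((b, l_s, n_s), dtype=np.int64)
    summary_in = np.zeros((b, t), dtype=np.int64)
    summary_tgt = np.zeros((b, t), dtype=np.int64)
    for i, e in enumerate(encoded):
        question[i, : len(e.question)] = e.question
        question_ext[i, : len(e.question)] = e.question_ext
        for j, (s, s_ext) in enumerate(zip(e.sentences, e.sentences_ext)):
            sentences[i, j, : len(s)] = s
            sentences_ext[i, j, : len(s)] = s_ext
        summary_in[i, 0] = BOS
        summary_in[i, 1 : 1 + len(e.summary)] = e.summary
        summary_tgt[i, : len(e.summary)] = e.summary_ext
        summary_tgt[i, len(e.summary)] = EOS
    question_mask = question_ext != PAD
    token_mask = sentences_ext != PAD
    sentence_mask = token_mask.any(axis=-1)
    summary_mask = summary_tgt != PAD
    n_oov = max(len(e.oov_map) for e in encoded)
    return Batch(
        question, question_ext, question_mask,
        sentences, sentences_ext, token_mask, sentence_mask,
        summary_in, summary_tgt, summary_mask,
        [e.label for e in encoded], n_oov, encoded,
    )


# -- file formats -----------------------------------------------------------


def read_pubmedqa(path) -> list[RawExample]:
    """Read the PubMedQA JSON release format.

    Instances map an id to {QUESTION, CONTEXTS, LONG_ANSWER, final_decision};
    CONTEXTS entries are sentence-split, LONG_ANSWER becomes the summary, and
    "maybe"-labeled instances are dropped (the task is framed yes/no).
    Instances missing a required field are skipped with a warning.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError("PubMedQA file must be a JSON object of instances")
    out: list[RawExample] = []
    required = ("QUESTION", "CONTEXTS", "LONG_ANSWER", "final_decision")
    for key, inst in data.items():
        if not isinstance(inst, dict) or any(f not in inst for f in required):
            logger.warning("skipping instance %s: missing required field", key)
            continue
        label = str(inst["final_decision"]).lower()
        if label == "maybe":
            continue
        sentences = [s for ctx in inst["CONTEXTS"] for s in split_sentences(str(ctx))]
        if not sentences:
            logger.warning("skipping instance %s: empty CONTEXTS", key)
            continue
        out.append(RawExample(str(inst["QUESTION"]), sentences, str(inst["LONG_ANSWER"]), label))
    return out


def read_jsonl(path) -> list[RawExample]:
    """Read the generic corpus dialect: one JSON object per line with keys
    question, sentences (list of strings), summary, label."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(
                RawExample(
                    obj["question"], list(obj["sentences"]), obj["summary"], obj.get("label")
                )
            )
    return out


def write_jsonl(examples, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(
                json.dumps(
                    {
                        "question": ex.question,
                        "sentences": ex.sentences,
                        "summary": ex.summary,
                        "label": ex.label,
                    }
                )
                + "\n"
            )
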