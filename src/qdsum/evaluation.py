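"""Evaluation suite: ROUGE-1/2/L, novel n-grams, LEAD3, QA consistency.

ROUGE preprocessing lowercases and splits punctuation into separate tokens;
no stemming or stopword removal by default. ROUGE-N uses clipped n-gram
overlap counts against a single reference; ROUGE-L uses the longest common
subsequence at summary level, F-measure with beta = 1.

The QA-based factual-consistency check trains a small transformer encoder
classifier on (question [SEP] text) pairs, reads out the [CLS] position,
and reports accuracy and macro-F1 together with the majority-class
baseline. Any backbone exposing the same train/predict surface can be
plugged in instead (e.g., a pretrained biomedical encoder); the built-in
one keeps the harness self-contained.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, gather_last, masked_softmax
from .config import ModelConfig, tiny_config
from .corpus import BOS, SEP, Vocabulary
from .nn import Adam, Embedding, Linear, Module, TransformerEncoder, bind_dropout_rng, sinusoidal_encoding

_TOKEN_RE = re.compile(r"[a-z0-9]+|[^\sa-z0-9]")


def rouge_tokenize(text, stem: bool = False) -> list[str]:
    """Lowercase, split punctuation into separate tokens."""
    if not isinstance(text, str):
        tokens = [str(t).lower() for t in text]
    else:
        tokens = _TOKEN_RE.findall(text.lower())
    if stem:
        tokens = [_light_stem(t) for t in tokens]
    return tokens


def _light_stem(token: str) -> str:
    for suffix in ("ing", "ed", "es", "s"):
        if token.endswith(suffix) and len(token) > len(suffix) + 2:
            return token[: -len(suffix)]
    return token


@dataclass
class ScoreTriple:
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0


@dataclass
class RougeScore:
    rouge1: ScoreTriple = field(default_factory=ScoreTriple)
    rouge2: ScoreTriple = field(default_factory=ScoreTriple)
    rougeL: ScoreTriple = field(default_factory=ScoreTriple)

    def to_dict(self) -> dict:
        return {
            name: vars(getattr(self, name)) for name in ("rouge1", "rouge2", "rougeL")
        }


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _rouge_n(cand: list[str], ref: list[str], n: int) -> ScoreTriple:
    cand_counts, ref_counts = _ngrams(cand, n), _ngrams(ref, n)
    overlap = sum((cand_counts & ref_counts).values())
    total_c, total_r = sum(cand_counts.values()), sum(ref_counts.values())
    p = overlap / total_c if total_c else 0.0
    r = overlap / total_r if total_r else 0.0
    return ScoreTriple(p, r, _f1(p, r))


def _lcs_length(a: list[str], b: list[str]) -> int:
    """Longest common subsequence via one-row dynamic programming."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        for j, y in enumerate(b, 1):
            curr.append(prev[j - 1] + 1 if x == y else max(prev[j], curr[-1]))
        prev = curr
    return prev[-1]


def rouge(candidate, reference, stem: bool = False) -> RougeScore:
    """ROUGE-1/2/L between one candidate and one reference summary."""
    cand = rouge_tokenize(candidate, stem)
    ref = rouge_tokenize(reference, stem)
    if not cand or not ref:
        return RougeScore()
    lcs = _lcs_length(cand, ref)
    p, r = lcs / len(cand), lcs / len(ref)
    return RougeScore(
        _rouge_n(cand, ref, 1), _rouge_n(cand, ref, 2), ScoreTriple(p, r, _f1(p, r))
    )


def corpus_rouge(candidates, references, stem: bool = False) -> RougeScore:
    """Mean P/R/F over paired candidate/reference lists."""
    scores = [rouge(c, r, stem) for c, r in zip(candidates, references)]
    out = RougeScore()
    if not scores:
        return out
    for name in ("rouge1", "rouge2", "rougeL"):
        for metric in ("precision", "recall", "f1"):
            value = float(np.mean([getattr(getattr(s, name), metric) for s in scores]))
            setattr(getattr(out, name), metric, value)
    return out


def novel_ngram_proportion(summaries, sources, n: int) -> float:
    """Percentage of summary n-gram tokens absent from the paired source.

    Corpus-level micro-average: summed over pairs, each summary n-gram
    occurrence counts once; a summary shorter than n contributes nothing.
    """
    novel, total = 0, 0
    for summary, source in zip(summaries, sources):
        s_tokens = rouge_tokenize(summary)
        src_ngrams = set(_ngrams(rouge_tokenize(source), n))
        for i in range(len(s_tokens) - n + 1):
            total += 1
            if tuple(s_tokens[i : i + n]) not in src_ngrams:
                novel += 1
    return 100.0 * novel / total if total else 0.0


def lead3(sentences: list[str]) -> str:
    """Extractive baseline: first two sentences plus the last sentence."""
    if not sentences:
        raise ValueError("document has no sentences")
    if len(sentences) <= 3:
        return " ".join(sentences)
    return " ".join([sentences[0], sentences[1], sentences[-1]])


# -- QA-based factual consistency -------------------------------------------


@dataclass
class ConsistencyReport:
    accuracy: float          # percent
    macro_f1: float          # percent
    confusion: np.ndarray    # rows gold (yes, no) x cols predicted (yes, no)
    majority_accuracy: float
    majority_macro_f1: float


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> tuple[float, float]:
    """(accuracy %, macro-F1 %) from a 2x2 confusion matrix.

    tp/fn are gold-yes rows, fp/tn gold-no; classes with no gold and no
    predicted members are excluded from the macro average.
    """
    total = tp + fn + fp + tn
    accuracy = 100.0 * (tp + tn) / total if total else 0.0
    f1s = []
    for tpos, fneg, fpos in ((tp, fn, fp), (tn, fp, fn)):  # yes view, no view
        if tpos + fneg + fpos == 0:
            continue
        p = tpos / (tpos + fpos) if tpos + fpos else 0.0
        r = tpos / (tpos + fneg) if tpos + fneg else 0.0
        f1s.append(_f1(p, r))
    macro = 100.0 * float(np.mean(f1s)) if f1s else 0.0
    return accuracy, macro


class TransformerClassifier(Module):
    """Small from-scratch encoder classifier for the QA harness.

    Input is ``[CLS] question [SEP] text``; the [CLS]-position state feeds a
    linear softmax head over {yes, no}.
    """

    def __init__(self, vocab_size: int, config: ModelConfig, seed: int = 13):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.embedding = Embedding(vocab_size, config.d_model, rng)
        self.encoder = TransformerEncoder(
            config.n_enc_layers, config.d_model, config.ffn_dim, config.n_heads,
            rng, config.dropout,
        )
        self.head = Linear(config.d_model, 2, rng)

    def logits(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        pe = sinusoidal_encoding(ids.shape[1], self.config.d_model)
        hidden = self.encoder(self.embedding(ids) + pe[None, :, :], mask)
        return self.head(hidden[:, 0, :])  # [CLS] position

    def predict(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        self.eval()
        return np.argmax(self.logits(ids, mask).data, axis=-1)  # 0 = yes, 1 = no


def _encode_pairs(pairs, vocab: Vocabulary, max_len: int = 128):
    ids_list = []
    for question, text, _ in pairs:
        ids = [BOS] + vocab.encode(question) + [SEP] + vocab.encode(text)
        ids_list.append(ids[:max_len])
    width = max(len(i) for i in ids_list)
    ids = np.zeros((len(ids_list), width), dtype=np.int64)
    for row, seq in zip(ids, ids_list):
        row[: len(seq)] = seq
    labels = np.array([0 if p[2] == "yes" else 1 for p in pairs], dtype=np.int64)
    return ids, ids != 0, labels


def train_qa_classifier(pairs, vocab: Vocabulary, config: ModelConfig | None = None,
                        seed: int = 13, steps: int = 200, batch_size: int = 32,
                        lr: float = 1e-3) -> TransformerClassifier:
    """Cross-entropy training of the [CLS] softmax head (and backbone)."""
    config = config or tiny_config()
    model = TransformerClassifier(len(vocab), config, seed)
    rng = np.random.default_rng(seed + 1)
    model.train()
    bind_dropout_rng(model, np.random.default_rng(seed + 2))
    ids, mask, labels = _encode_pairs(pairs, vocab)
    opt = Adam(model.parameters(), lr=lr, clip_norm=None)
    n = len(pairs)
    step = 0
    while step < steps:
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            if step >= steps:
                break
            sel = order[start : start + batch_size]
            logits = model.logits(ids[sel], mask[sel])
            probs = masked_softmax(logits, np.ones(logits.shape, dtype=bool))
            gold = gather_last(probs.clip_min(1e-12).log(), labels[sel][:, None])
            loss = -gold.mean()
            model.zero_grad()
            loss.backward()
            opt.step()
            step += 1
    model.eval()
    return model


def qa_consistency(pairs, train_fraction: float = 0.8, config: ModelConfig | None = None,
                   seed: int = 13, steps: int = 200,
                   classifier: TransformerClassifier | None = None,
                   vocab: Vocabulary | None = None) -> ConsistencyReport:
    """Train/evaluate the yes-no classifier on (question, text, label) pairs.

    ``classifier``/``vocab`` may be supplied to evaluate a pre-trained
    backbone; otherwise the built-in small transformer is trained on the
    first ``train_fraction`` of a seeded shuffle and evaluated on the rest.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to split train/test")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    cut = max(1, int(round(train_fraction * len(pairs))))
    cut = min(cut, len(pairs) - 1)
    train_pairs = [pairs[i] for i in order[:cut]]
    test_pairs = [pairs[i] for i in order[cut:]]
    if vocab is None:
        words = set()
        for q, t, _ in pairs:
            words.update(q.split())
            words.update(t.split())
        vocab = Vocabulary.from_tokens(sorted(words))
    if classifier is None:
        classifier = train_qa_classifier(train_pairs, vocab, config, seed, steps)
    ids, mask, gold = _encode_pairs(test_pairs, vocab)
    pred = classifier.predict(ids, mask)
    tp = int(np.sum((gold == 0) & (pred == 0)))
    fn = int(np.sum((gold == 0) & (pred == 1)))
    fp = int(np.sum((gold == 1) & (pred == 0)))
    tn = int(np.sum((gold == 1) & (pred == 1)))
    accuracy, macro = metrics_from_confusion(tp, fn, fp, tn)
    majority = 0 if np.sum(gold == 0) >= np.sum(gold == 1) else 1
    mtp = int(np.sum(gold == 0)) if majority == 0 else 0
    mfn = 0 if majority == 0 else int(np.sum(gold == 0))
    mfp = int(np.sum(gold == 1)) if majority == 0 else 0
    mtn = 0 if majority == 0 else int(np.sum(gold == 1))
    maj_acc, maj_f1 = metrics_from_confusion(mtp, mfn, mfp, mtn)
    return ConsistencyReport(
        accuracy, macro, np.array([[tp, fn], [fp, tn]]), maj_acc, maj_f1
    )
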