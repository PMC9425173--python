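# Methods

## Model

The summarizer is a transformer encoder–decoder specialized for
question-driven summarization. Its assumptions, in order of importance:

- **The answer is localized.** Coattention assumes a small number of
  document sentences carry the material the question asks about; the
  sentence relevance distribution `α` doubles as the pointer's global
  document distribution, so sentence-level relevance directly shapes
  token-level copying.
- **Cross-sentence context matters at the token level.** Intersentence
  attention injects a per-sentence context vector (computed over pooled
  sentence representations) back into every token state before any
  question matching happens, so sentence vectors fed to coattention already
  carry document-wide information.
- **Copying is a first-class generation mode.** Biomedical text has a heavy
  out-of-vocabulary tail; the three-view mixture lets probability mass reach
  source tokens that the vocabulary softmax cannot express. The mixture is
  computed in probability space (not log space) so the final distribution is
  an exact convex combination of the three views.

Architectural choices where the design was genuinely open:

- **Positional encodings.** Token positions use fixed sinusoids and restart
  at 0 inside each sentence (sentences are encoded one by one); sentence
  order uses a learned embedding table. Both follow standard transformer
  practice for hierarchical inputs.
- **Post-norm layers.** Residual-then-LayerNorm, the original transformer
  arrangement.
- **Separate encoder weights.** The question and sentence encoders share the
  token-embedding table (also tied to the decoder input and the vocabulary
  softmax) but have separate transformer weights; `share_encoders=True`
  collapses them.
- **Three-way gating as two pairwise gates.** The integration gate is
  defined pairwise, so the attentive question and document are gated first
  and the result is gated with the correlative summary.
- **Cross-attention per decoder layer.** Each decoder layer runs the full
  self-attention → cross-attention → gating block; `cross_attn="final-only"`
  moves cross-attention and gating after the stack. The pointer always reads
  its attention weights (`β^q`, `β^s`) from the final cross-attention block,
  averaged over heads.
- **Copy-distribution normalization.** Scatter-added copy weights are
  renormalized after combining the global and local factors (`p^s`) and
  after scatter-adding duplicates (`p^q`, `p^s`), keeping each view a proper
  distribution regardless of repeated source tokens.
- **Multi-head pooling scope.** Pooling probabilities are per head, per
  sentence, over that sentence's tokens only.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d_model` | 256 | embedding and hidden width |
| `ffn_dim` | 512 | feed-forward width |
| `n_heads` | 4 | attention heads (d_head = 64) |
| `n_enc_layers` / `n_dec_layers` | 5 / 5 | encoder / decoder depth |
| `dropout` | 0.2 | on attention outputs and FFN outputs, training only |
| `label_smoothing` | 0.1 | smoothing mass, spread over the fixed vocabulary only |
| `lr`, `warmup` | 5e-4, 5000 | peak Adam rate; linear warmup then inverse-sqrt decay |
| `grad_clip` | 0.1 | global gradient-norm bound |
| `beam`, `block_ngram` | 2, 3 | beam width; repeated-n-gram blocking |
| `max_q` / `max_sent_len` / `max_sents` / `max_summary` | 60 / 100 / 20 / 100 | truncation limits (cover the corpus averages with headroom) |

Adam uses β=(0.9, 0.998), ε=1e-9; batch size defaults to 32 examples.
Checkpoint selection uses validation token-mean NLL when a validation set is
given. Label smoothing excludes extended ids because their support varies
per example; a fixed-support smoothing target keeps the loss well defined.
Gold tokens assigned zero final probability are clamped at 1e-12 in the log
and counted (`TrainState.clamp_events`).

Tests and the worked examples use `tiny_config()` (d=32, 64 FFN, 2 heads,
2+2 layers, dropout 0, warmup 50); fixtures that need memorization raise the
peak rate to 2e-3 and disable smoothing. These are desk-scale choices for a
model whose full-scale settings are the table above.

## Numerical core

The network runs on a small reverse-mode autodiff engine over numpy float64
arrays (`qdsum.autodiff`): a define-by-run tape with hand-written backward
rules for each primitive (masked softmax, layer norm, embedding gather,
scatter-sum for copy distributions, gelu via the exact erf form). Every
backward rule is verified against central finite differences in the test
suite. Masked softmax gives exactly zero probability to masked positions and
returns an all-zero row when nothing is valid; downstream reductions mask
such rows out, which is what makes padding-perturbation invariance an exact
property rather than an approximation. Beam search stops only when no live
hypothesis can still beat the best finished score (a live hypothesis's log
probability never increases; under length normalization the bound is
`logprob / max_len`), and score ties break toward the lower token id so
decoding is fully deterministic.

## Synthetic corpora

`qdsum.synthetic_data` generates corpora with the aggregate shape of the
real data: mean question length 16.3 words, 9.32 sentences per document,
238 document words, 41.0 summary words, and a 92.8/7.2 yes/no split.
Lengths are Poisson around those means (simple, positive, reproducible);
labels are Bernoulli. Each summary mixes *copied* tokens (planted verbatim
in one uniformly-placed answer-bearing sentence, which also repeats a few
question tokens so coattention has a learnable signal) with *novel* tokens
drawn from a pool that never appears in documents. `copy_rate` defaults to
0.72, matching the ~28% novel-unigram rate of real reference summaries;
`oov_rate` controls how many source content tokens fall outside the model
vocabulary. The answer-bearing sentence keeps all its planted tokens even
when that exceeds its sampled length, so realized document length runs a few
percent above the configured mean.

What the generator does *not* emulate: biomedical vocabulary and semantics
(tokens are abstract symbols), discourse structure, paraphrase between
source and summary, and label noise (the yes/no label is a deterministic
function of a negation cue token). Consequently, passing tests demonstrate
that the mechanisms work — the pointer really copies out-of-vocabulary
tokens, coattention really finds the answer-bearing sentence, the gates and
masks are correct — but say nothing about ROUGE levels reachable on real
biomedical text, which require full-scale training on the real corpus.

## Evaluation suite

ROUGE-1/2/L are computed from scratch (clipped n-gram overlap; summary-level
LCS with β=1 F-measure) over lowercased, punctuation-split tokens, no
stemming by default; the test suite checks agreement with an independently
written reference computation. Novel n-gram proportions are corpus-level
micro-averages per n-gram occurrence. LEAD3 concatenates the first two
sentences and the last sentence (whole document, in order, when it has at
most three). The QA consistency harness forms `[CLS] question [SEP] text`,
trains a small from-scratch transformer classifier by cross-entropy, and
reports accuracy, macro-F1, the 2×2 confusion matrix, and the majority-class
baseline; a pretrained biomedical encoder can be plugged in through the
`classifier`/`vocab` arguments of `qa_consistency`.

## Problem sizes

The shipped measurements are deliberately small: the overfitting fixture
uses 16 examples (vocab 120, question ≈6 words, 3 sentences, summary ≈8
words) and a tiny model; the copy-mechanism study uses 32 examples with
copy_rate 0.9 / oov_rate 0.3 over 3 seeds; corpus statistics use 10,000
examples; the QA harness uses 500 pairs. These sizes make every result
recomputable in minutes on one CPU while still exercising each mechanism
end to end.

## Known limitations

- No incremental decoder caching: beam search re-encodes the prefix each
  step (quadratic in summary length; irrelevant at desk scale).
- No coverage mechanism, no pretrained embedding or encoder initialization
  (a word→vector hook and the pluggable QA backbone are the extension
  points), no multi-device training.
- The BPE trainer is the classical frequency-merge algorithm with
  lexicographic tie-breaks; it is deterministic but not optimized for large
  corpora.
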