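"""Training objective and loop.

The objective is token-mean negative log likelihood of the gold extended-id
sequence under the mixture distribution, with label smoothing whose mass is
spread over the fixed vocabulary only (extended ids vary per example, so a
fixed-support smoothing target keeps the loss well defined). Optimization is
Adam with an inverse-square-root learning-rate schedule after linear warmup
and global-norm gradient clipping.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, gather_last
from .config import ModelConfig
from .corpus import Batch, Example, Limits, Vocabulary, make_batch, make_example
from .model import Summarizer
from .nn import Adam

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12  # log clamp for gold tokens the mixture assigns zero mass


def nll_loss(final: Tensor, gold_ids: np.ndarray, mask: np.ndarray,
             vocab_size: int, smoothing: float = 0.0) -> tuple[Tensor, int]:
    """Label-smoothed NLL over valid target positions.

    Per token: -[(1 - eps) * log P(gold) + eps * mean_{w in V} log P(w)],
    averaged over non-pad positions. Returns the scalar loss and the number
    of gold tokens whose probability hit the clamp floor.
    """
    if gold_ids.size == 0 or not mask.any():
        raise ValueError("empty gold sequence")
    gold_p = np.take_along_axis(final.data, gold_ids[..., None], axis=-1)
    clamped = int(np.sum((gold_p <= PROB_FLOOR) & mask[..., None]))
    log_p = final.clip_min(PROB_FLOOR).log()
    gold_term = gather_last(log_p, gold_ids[..., None]).reshape(gold_ids.shape)
    per_token = -gold_term if smoothing == 0.0 else -(
        (1.0 - smoothing) * gold_term
        + smoothing * log_p[..., :vocab_size].mean(axis=-1)
    )
    count = float(mask.sum())
    loss = per_token.mask(mask).sum() / count
    return loss, clamped


def lr_schedule(step: int, lr_base: float, warmup: int) -> float:
    """Linear warmup then inverse square root decay; peak lr_base at warmup."""
    if step < 1:
        raise ValueError("step must be >= 1")
    return lr_base * min(step / warmup, math.sqrt(warmup / step))


@dataclass
class TrainState:
    model: Summarizer
    step: int = 0
    lr: float = 0.0
    running_nll: float = float("inf")
    best_val_nll: float = float("inf")
    best_state: dict | None = field(default=None, repr=False)
    clamp_events: int = 0
    history: list[dict] = field(default_factory=list)


def _iter_batches(examples: list[Example], vocab: Vocabulary, batch_size: int,
                  rng: np.random.Generator):
    order = rng.permutation(len(examples))
    for start in range(0, len(examples), batch_size):
        chunk = [examples[i] for i in order[start : start + batch_size]]
        yield make_batch(chunk, vocab)


def evaluate_nll(model: Summarizer, examples: list[Example], vocab: Vocabulary,
                 batch_size: int = 32) -> float:
    """Token-mean NLL (no smoothing) of a corpus under the current model."""
    model.eval()
    total, count = 0.0, 0
    for start in range(0, len(examples), batch_size):
        batch = make_batch(examples[start : start + batch_size], vocab)
        dist = model(batch)
        loss, _ = nll_loss(dist.final, batch.summary_tgt, batch.summary_mask,
                           model.vocab_size, smoothing=0.0)
        n = int(batch.summary_mask.sum())
        total += loss.item() * n
        count += n
    return total / max(count, 1)


def train(examples, vocab: Vocabulary, config: ModelConfig, *, seed: int = 13,
          steps: int = 1000, val_examples=None, run_dir=None,
          limits: Limits | None = None, log_every: int = 50, val_every: int = 200,
          target_nll: float | None = None, model: Summarizer | None = None) -> TrainState:
    """Train a summarizer; deterministic given ``seed`` on one device.

    ``target_nll`` stops early once the running token-mean NLL drops below
    it (used by desk-scale fixtures). The best-validation checkpoint (by
    token-mean NLL) is kept in memory and written to ``run_dir`` if given.
    """
    encoded = [
        ex if isinstance(ex, Example) else make_example(ex, vocab, limits) for ex in examples
    ]
    if not encoded:
        raise ValueError("empty training corpus")
    val = None
    if val_examples is not None:
        val = [
            ex if isinstance(ex, Example) else make_example(ex, vocab, limits)
            for ex in val_examples
        ]
    seeds = np.random.SeedSequence(seed).spawn(3)
    data_rng = np.random.default_rng(seeds[0])
    if model is None:
        model = Summarizer(len(vocab), config, seed=int(seeds[1].generate_state(1)[0] % (2**31)))
    model.bind_rng(np.random.default_rng(seeds[2]))
    opt = Adam(model.parameters(), lr=config.lr, betas=config.adam_betas,
               eps=config.adam_eps, clip_norm=config.grad_clip)
    state = TrainState(model)
    run_dir = Path(run_dir) if run_dir is not None else None
    log_fh = None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(run_dir / "config.yaml")
        log_fh = open(run_dir / "log.jsonl", "w", encoding="utf-8")
    try:
        ema = None
        while state.step < steps:
            for batch in _iter_batches(encoded, vocab, config.batch_size, data_rng):
                if state.step >= steps:
                    break
                state.step += 1
                state.lr = lr_schedule(state.step, config.lr, config.warmup)
                opt.lr = state.lr
                model.train()
                dist = model(batch)
                loss, clamped = nll_loss(
                    dist.final, batch.summary_tgt, batch.summary_mask,
                    model.vocab_size, config.label_smoothing,
                )
                state.clamp_events += clamped
                value = loss.item()
                if not math.isfinite(value):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at step {state.step}"
                    )
                model.zero_grad()
                loss.backward()
                opt.clip_gradients()
                opt.step()
                ema = value if ema is None else 0.9 * ema + 0.1 * value
                state.running_nll = ema
                if state.step % log_every == 0 or state.step == steps:
                    record = {"step": state.step, "lr": state.lr, "loss": value,
                              "running_nll": ema}
                    state.history.append(record)
                    if log_fh:
                        log_fh.write(json.dumps(record) + "\n")
                if val is not None and state.step % val_every == 0:
                    val_nll = evaluate_nll(model, val, vocab, config.batch_size)
                    if val_nll < state.best_val_nll:
                        state.best_val_nll = val_nll
                        state.best_state = model.state_dict()
                if target_nll is not None and ema is not None and ema < target_nll:
                    break
            else:
                continue
            break
    finally:
        if log_fh:
            log_fh.close()
    if val is not None and state.best_state is None:
        state.best_val_nll = evaluate_nll(model, val, vocab, config.batch_size)
        state.best_state = model.state_dict()
    model.eval()
    if run_dir is not None:
        if state.best_state is not None:
            model.load_state_dict(state.best_state)
        model.save(run_dir / "checkpoint.npz")
    return state
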