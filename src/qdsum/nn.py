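"""Neural-network building blocks: modules, transformer layers, optimizer.

Parameters are plain :class:`~qdsum.autodiff.Tensor` objects with
``requires_grad=True``; a :class:`Module` tree collects them by name so
checkpoints are flat ``name -> array`` dicts. Initialization draws from an
explicit ``numpy.random.Generator`` in construction order, so a seed fixes
the parameters exactly.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, embedding, layer_norm, masked_softmax

NEG_INF = -1e30  # additive mask value; large but finite to keep grads clean


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def _param(array: np.ndarray) -> Tensor:
    return Tensor(array, requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = math.sqrt(6.0 / (d_in + d_out))
        self.weight = _param(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = _param(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _param(rng.normal(0.0, d**-0.5, size=(n, d)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = _param(np.ones(d))
        self.beta = _param(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    """Inverted dropout; active only in training mode. ``rng`` is bound late
    (by the owning model) so one run seed drives every dropout mask."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without a bound rng")
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep


def bind_dropout_rng(root: Module, rng: np.random.Generator) -> None:
    for m in root.modules():
        if isinstance(m, Dropout):
            m.rng = rng


def sinusoidal_encoding(length: int, d: int) -> np.ndarray:
    """Fixed sin/cos positional encoding, interleaved: pe(0) = [0,1,0,1,...]."""
    position = np.arange(length)[:, None]
    div = np.exp(np.arange(0, d, 2) * (-math.log(10000.0) / d))
    pe = np.zeros((length, d))
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div)
    return pe


class MultiHeadAttention(Module):
    """Scaled dot-product attention with head split/merge.

    Returns the attended output and the per-head attention weights
    ``[B, h, Tq, Tk]`` (needed by the pointer views).
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        if d % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d, self.h, self.dk = d, n_heads, d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.drop = Dropout(dropout)

    def __call__(
        self,
        query: Tensor,
        key_value: Tensor,
        kv_mask: np.ndarray,
        causal: bool = False,
    ) -> tuple[Tensor, Tensor]:
        b, tq, _ = query.shape
        tk = key_value.shape[1]
        q = self.wq(query).reshape(b, tq, self.h, self.dk).transpose(0, 2, 1, 3)
        k = self.wk(key_value).reshape(b, tk, self.h, self.dk).transpose(0, 2, 1, 3)
        v = self.wv(key_value).reshape(b, tk, self.h, self.dk).transpose(0, 2, 1, 3)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (self.dk**-0.5)
        mask = np.asarray(kv_mask, dtype=bool)[:, None, None, :]  # [B,1,1,Tk]
        mask = np.broadcast_to(mask, (b, 1, tq, tk))
        if causal:
            tri = np.tril(np.ones((tq, tk), dtype=bool))
            mask = mask & tri[None, None, :, :]
        attn = masked_softmax(logits, mask, axis=-1)
        out = attn @ v  # [B,h,Tq,dk]
        out = out.transpose(0, 2, 1, 3).reshape(b, tq, self.d)
        return self.drop(self.wo(out)), attn


class FeedForward(Module):
    def __init__(self, d: int, d_ffn: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.w1 = Linear(d, d_ffn, rng)
        self.w2 = Linear(d_ffn, d, rng)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.w2(self.w1(x).relu()))


class GeluMLP(Module):
    """Two-layer perceptron with gelu activation (the fusion MLP form)."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.w1 = Linear(d_in, d_hidden, rng)
        self.w2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(self.w1(x).gelu())


class TransformerEncoderLayer(Module):
    """Post-norm transformer layer: self-attention + FFN, residuals + LN."""

    def __init__(self, d: int, d_ffn: int, n_heads: int, rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.attn = MultiHeadAttention(d, n_heads, rng, dropout)
        self.ffn = FeedForward(d, d_ffn, rng, dropout)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        attn_out, _ = self.attn(x, x, mask)
        x = self.ln1(x + attn_out)
        return self.ln2(x + self.ffn(x))


class TransformerEncoder(Module):
    def __init__(self, n_layers: int, d: int, d_ffn: int, n_heads: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.layers = [
            TransformerEncoderLayer(d, d_ffn, n_heads, rng, dropout) for _ in range(n_layers)
        ]

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        for layer in self.layers:
            x = layer(x, mask)
        return x


def masked_mean(x: Tensor, mask: np.ndarray, axis: int) -> Tensor:
    """Mean of ``x`` over ``axis`` counting only positions where mask is True."""
    m = np.asarray(mask, dtype=np.float64)
    while m.ndim < x.ndim:
        m = m[..., None]
    count = np.maximum(m.sum(axis=axis), 1.0)
    return (x * m).sum(axis=axis) / count


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.998), eps: float = 1e-9,
                 clip_norm: float | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def grad_norm(self) -> float:
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float(np.sum(p.grad**2))
        return math.sqrt(total)

    def clip_gradients(self) -> float:
        """Scale all gradients so the global norm is at most ``clip_norm``."""
        norm = self.grad_norm()
        if self.clip_norm is not None and norm > self.clip_norm:
            scale = self.clip_norm / (norm + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return norm

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
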