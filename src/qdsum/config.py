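"""Model hyperparameters and their serialization."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults are the full-scale settings (256-d embeddings and hidden
    states, 512 feed-forward width, 4 heads, 5+5 layers, dropout 0.2,
    label smoothing 0.1, Adam at 5e-4 with a 5k-step inverse-square-root
    warmup, gradient norm clipped at 0.1, beam 2 with trigram blocking).
    Tests and the worked examples shrink them.
    """

    d_model: int = 256
    ffn_dim: int = 512
    n_heads: int = 4
    n_enc_layers: int = 5
    n_dec_layers: int = 5
    dropout: float = 0.2
    label_smoothing: float = 0.1
    lr: float = 0.0005
    warmup: int = 5000
    grad_clip: float = 0.1
    beam: int = 2
    block_ngram: int = 3
    max_sents: int = 20
    batch_size: int = 32
    adam_betas: tuple[float, float] = (0.9, 0.998)
    adam_eps: float = 1e-9
    # ablation switches (all on = full model)
    intersentence: bool = True
    coattention: bool = True
    overall_integration: bool = True
    multiview_pointer: bool = True
    # open-design flags
    share_encoders: bool = False       # separate transformer weights per encoder
    cross_attn: str = "per-layer"      # or "final-only"

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("dropout", "label_smoothing"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.warmup < 1:
            raise ValueError("warmup must be >= 1")
        if self.cross_attn not in ("per-layer", "final-only"):
            raise ValueError("cross_attn must be 'per-layer' or 'final-only'")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["adam_betas"] = list(self.adam_betas)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "adam_betas" in data:
            data["adam_betas"] = tuple(data["adam_betas"])
        return cls(**data)


def tiny_config(**overrides) -> ModelConfig:
    """A desk-scale configuration used by tests and worked examples."""
    base = dict(
        d_model=32, ffn_dim=64, n_heads=2, n_enc_layers=2, n_dec_layers=2,
        dropout=0.0, warmup=50, batch_size=16,
    )
    base.update(overrides)
    return ModelConfig(**base)
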