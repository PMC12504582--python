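"""Flat, YAML-serializable experiment configuration.

One :class:`ExperimentConfig` captures everything a run needs —
generator settings, encoder size, training recipe, fold and
learning-curve parameters, output directory and the single global seed
— so that a saved config re-runs the identical experiment.  All
randomness in the pipeline flows from ``seed``; there are no hidden
entropy sources.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .lexicon import Lexicon, builtin_lexicon, load_lexicon
from .model import EncoderSpec
from .synthgen import GeneratorConfig
from .training import LearningCurveConfig, TrainingConfig

__all__ = ["ExperimentConfig"]


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one experiment, flat and fully serializable."""

    seed: int = 0
    output_dir: str = "madrscore-run"
    log_level: str = "INFO"
    corpus_path: Optional[str] = None

    # synthetic corpus generator
    counts: int = 15
    signal_strength: float = 1.0
    noise_prob: float = 0.0
    turns_per_dialog: int = 4
    lexicon: str = "token"  # "token", "german", or a YAML/JSON path
    min_per_cell: int = 15

    # encoder size (desk-scale defaults)
    num_layers: int = 2
    hidden_dim: int = 64
    num_attention_heads: int = 4
    max_sequence_length: int = 64
    pretrained_ref: Optional[str] = None

    # training: "desk_scale" (from-scratch tiny encoder) or "published"
    training_preset: str = "desk_scale"
    max_epochs: Optional[int] = None
    learning_rate: Optional[float] = None

    # cross-validation and learning curve
    k: int = 5
    fractions: tuple[float, ...] = (0.05, 0.10, 0.20, 0.35, 0.50, 0.65, 0.80)

    # ------------------------------------------------------------ factories

    def lexicon_obj(self) -> Lexicon:
        if self.lexicon in ("token", "german"):
            return builtin_lexicon(self.lexicon)
        return load_lexicon(self.lexicon)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            counts=self.counts,
            signal_strength=self.signal_strength,
            noise_prob=self.noise_prob,
            turns_per_dialog=self.turns_per_dialog,
            seed=self.seed,
            lexicon=self.lexicon_obj(),
        )

    def encoder_spec(self, vocab_size: int) -> EncoderSpec:
        return EncoderSpec(
            vocab_size=vocab_size,
            num_layers=self.num_layers,
            hidden_dim=self.hidden_dim,
            num_attention_heads=self.num_attention_heads,
            max_sequence_length=self.max_sequence_length,
            pretrained_ref=self.pretrained_ref,
        )

    def training_config(self) -> TrainingConfig:
        if self.training_preset == "published":
            cfg = TrainingConfig(seed=self.seed)
        elif self.training_preset == "desk_scale":
            cfg = TrainingConfig.desk_scale(seed=self.seed)
        else:
            raise ValueError(f"unknown training preset {self.training_preset!r}")
        if self.max_epochs is not None:
            cfg = replace(
                cfg,
                max_epochs=self.max_epochs,
                early_stopping_patience=min(cfg.early_stopping_patience, self.max_epochs),
            )
        if self.learning_rate is not None:
            cfg = replace(cfg, learning_rate=self.learning_rate)
        return cfg

    def learning_curve_config(self) -> LearningCurveConfig:
        return LearningCurveConfig(fractions=self.fractions, k=self.k, seed=self.seed)

    # -------------------------------------------------------- serialization

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fractions" in data:
            data["fractions"] = tuple(float(f) for f in data["fractions"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fractions"] = list(data["fractions"])
        Path(path).write_text(
            yaml.safe_dump(data, sort_keys=False), encoding="utf-8"
        )

    def with_overrides(self, **kwargs) -> "ExperimentConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self
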