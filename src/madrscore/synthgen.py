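"""Deterministic generator of balanced synthetic interview corpora.

Real MADRS interview corpora are both private and badly imbalanced:
severe scores are rare.  This module stands in for such data with a
template generator that (a) hits any requested count per
``(item, score)`` cell exactly, and (b) plants a *score-monotone
lexical signal* whose strength is controlled explicitly, so that model
and pipeline behavior can be studied under known conditions.

Noise model
-----------
Each patient utterance is drawn from a severity band ``b``:

* with probability ``noise_prob`` the band is a uniformly random
  *wrong* band (``b != score``);
* otherwise ``b = round(score * s + u * (1 - s))`` where
  ``s = signal_strength`` and ``u`` is a uniform integer on {0..6}.

``s = 1`` makes the band equal the true score; ``s = 0`` makes it a
uniform draw independent of the score.  The integer-``u`` choice keeps
the zero-signal band distribution exactly uniform.  This linear
band-mixing model is the package's own construction; it exists to give
tests a dial between "perfectly separable" and "pure noise".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

from .corpus import Corpus, ItemSample, MadrsItem, SCORES
from .lexicon import BAND_MARKER_RE, Lexicon, PhraseBank, token_lexicon

__all__ = ["GeneratorConfig", "generate_sample", "generate_balanced_corpus", "emitted_bands"]

CellCounts = Mapping[tuple[int, int], int]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for the synthetic corpus generator.

    Parameters
    ----------
    counts
        Either one integer (the same target count for all 63
        ``(item, score)`` cells) or a mapping ``{(item_id, score): n}``
        covering all cells.  The default of 15 per cell mirrors the
        minimum-interviews-per-score-and-item balancing constraint and
        yields a 945-sample corpus.
    signal_strength
        In [0, 1].  How strongly the emitted severity band tracks the
        true score; 0 means no signal at all.
    noise_prob
        In [0, 1].  Probability that an utterance is drawn from a
        uniformly random wrong band.
    turns_per_dialog
        Total dialog turns including the opening probe question
        (so ``turns_per_dialog - 1`` patient utterances); minimum 2.
    seed
        Base seed; the generator is fully deterministic given
        (config, seed).
    lexicon
        Per-item phrase banks; defaults to the synthetic token lexicon.
    """

    counts: Union[int, CellCounts] = 15
    signal_strength: float = 1.0
    noise_prob: float = 0.0
    turns_per_dialog: int = 4
    seed: int = 0
    lexicon: Optional[Lexicon] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not 0.0 <= self.noise_prob <= 1.0:
            raise ValueError("noise_prob must lie in [0, 1]")
        if self.turns_per_dialog < 2:
            raise ValueError("turns_per_dialog must be at least 2")
        if isinstance(self.counts, int):
            if self.counts < 0:
                raise ValueError("counts must be non-negative")
        else:
            for (item, score), n in self.counts.items():
                if n < 0:
                    raise ValueError(f"count for cell ({item}, {score}) is negative")

    def cell_count(self, item: MadrsItem, score: int) -> int:
        if isinstance(self.counts, int):
            return self.counts
        try:
            return self.counts[(int(item), score)]
        except KeyError as exc:
            raise ValueError(f"no count specified for cell ({int(item)}, {score})") from exc

    def bank(self, item: MadrsItem) -> PhraseBank:
        lex = self.lexicon if self.lexicon is not None else _DEFAULT_LEXICON
        try:
            return lex[item]
        except KeyError as exc:
            raise ValueError(f"no phrase bank for item {int(item)}") from exc


_DEFAULT_LEXICON = token_lexicon()


def _draw_band(score: int, config: GeneratorConfig, rng: np.random.Generator) -> int:
    if config.noise_prob > 0 and rng.random() < config.noise_prob:
        wrong = [b for b in SCORES if b != score]
        return int(rng.choice(wrong))
    u = int(rng.integers(0, 7))
    b = round(score * config.signal_strength + u * (1.0 - config.signal_strength))
    return int(min(max(b, 0), 6))


def generate_sample(
    item: MadrsItem,
    score: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    interview_id: Optional[str] = None,
) -> ItemSample:
    """Generate one synthetic item segment.

    The dialog opens with a probe question for the item followed by
    ``turns_per_dialog - 1`` patient utterances drawn under the band
    noise model described in the module docstring.  The stored score is
    always the *requested* score, whatever bands the noise produced.
    """
    if score not in SCORES:
        raise ValueError(f"score {score} outside 0-6")
    item = MadrsItem(item)
    bank = config.bank(item)
    lines = [f"INT: {bank.probes[int(rng.integers(0, len(bank.probes)))]}"]
    for _ in range(config.turns_per_dialog - 1):
        band = _draw_band(score, config, rng)
        phrases = bank.bands[band]
        lines.append(f"PAT: {phrases[int(rng.integers(0, len(phrases)))]}")
    return ItemSample(
        interview_id=interview_id or f"syn-{int(item)}-{score}",
        item=item,
        dialog="\n".join(lines),
        score=score,
        source="synthetic",
    )


def generate_balanced_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a corpus whose (item, score) counts match the config exactly.

    Iterates items x scores in a fixed order with one child random
    stream per cell (spawned deterministically from ``config.seed``),
    so the output is byte-identical for identical configs and
    independent of how counts are partitioned across cells.
    Interview ids follow the pattern ``syn-{item}-{score}-{index}``.
    """
    samples: list[ItemSample] = []
    for item in MadrsItem:
        for score in SCORES:
            n = config.cell_count(item, score)
            rng = np.random.default_rng([config.seed, int(item), score])
            for idx in range(n):
                samples.append(
                    generate_sample(
                        item,
                        score,
                        config,
                        rng,
                        interview_id=f"syn-{int(item)}-{score}-{idx}",
                    )
                )
    return Corpus(tuple(samples))


def emitted_bands(sample: ItemSample) -> list[int]:
    """Severity bands of a token-lexicon dialog's patient utterances.

    Parses the ``sev{b}`` markers that the token lexicon embeds in every
    utterance template; raises if none are present (e.g. for a natural
    language lexicon, where bands are not mechanically recoverable).
    """
    bands = [int(m) for m in BAND_MARKER_RE.findall(sample.dialog)]
    if not bands:
        raise ValueError("dialog carries no sev{b} markers (not a token-lexicon sample)")
    return bands
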