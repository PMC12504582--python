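"""Shared fixtures: token lexicon, tiny encoder, small synthetic corpora.

Everything is generated programmatically; the token lexicon keeps all
correctness checks independent of natural language.
"""

from __future__ import annotations

import numpy as np
import pytest

from madrscore import (
    Corpus,
    EncoderSpec,
    GeneratorConfig,
    ItemSample,
    MadrsItem,
    Tokenizer,
    generate_balanced_corpus,
    token_lexicon,
)


@pytest.fixture(scope="session")
def lexicon():
    return token_lexicon()


@pytest.fixture(scope="session")
def tokenizer(lexicon):
    return Tokenizer.from_lexicon(lexicon)


@pytest.fixture(scope="session")
def tiny_spec(tokenizer):
    return EncoderSpec.tiny(tokenizer.vocab_size)


@pytest.fixture(scope="session")
def small_corpus(lexicon):
    """189-sample balanced corpus (3 per cell), perfect planted signal."""
    return generate_balanced_corpus(
        GeneratorConfig(counts=3, signal_strength=1.0, noise_prob=0.0, seed=11, lexicon=lexicon)
    )


@pytest.fixture(scope="session")
def balanced_corpus_945(lexicon):
    """Study-scale balanced corpus: 15 per (item, score) cell, strong signal."""
    return generate_balanced_corpus(
        GeneratorConfig(counts=15, signal_strength=1.0, noise_prob=0.0, seed=7, lexicon=lexicon)
    )


def make_flat_corpus(n_per_cell: int = 1, items=None, scores=None) -> Corpus:
    """Minimal hand-built corpus (no generator) for combinatorial tests."""
    items = items if items is not None else list(MadrsItem)
    scores = scores if scores is not None else list(range(7))
    samples = []
    for item in items:
        for score in scores:
            for j in range(n_per_cell):
                samples.append(
                    ItemSample(
                        interview_id=f"iv-{int(item)}-{score}-{j}",
                        item=MadrsItem(item),
                        dialog=f"INT: probe\nPAT: sev{score} text",
                        score=score,
                    )
                )
    return Corpus(tuple(samples))
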