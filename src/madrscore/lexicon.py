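"""Phrase banks for the synthetic interview generator.

A :class:`PhraseBank` holds, for one MADRS item, a list of clinician
probe-question templates and seven severity *bands* of patient-utterance
templates — band ``b`` expresses symptom severity level ``b`` (0 = no
symptoms, 6 = most severe).

Two built-in lexicons ship with the package:

``token_lexicon``
    A language-independent vocabulary of synthetic tokens
    (``sev0`` … ``sev6`` severity markers plus filler tokens).  Fast
    and unambiguous; the test suite uses it so that correctness checks
    do not depend on any natural language.

``german_lexicon``
    A small German-flavored lexicon for human-readable demo corpora,
    combining per-item probe questions ("Wie haben Sie in der letzten
    Woche geschlafen?") with severity-graded complaint phrases.

Custom lexicons can be loaded from YAML or JSON files with the schema
``{item_id: {"probes": [...], "bands": [[...], ... 7 lists ...]}}``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .corpus import MadrsItem

__all__ = ["PhraseBank", "Lexicon", "token_lexicon", "german_lexicon", "load_lexicon", "BAND_MARKER_RE"]

N_BANDS = 7

#: Regex matching the severity markers emitted by the token lexicon.
BAND_MARKER_RE = re.compile(r"\bsev([0-6])\b")


@dataclass(frozen=True)
class PhraseBank:
    """Probe questions and severity-banded patient utterances for one item."""

    item: MadrsItem
    probes: tuple[str, ...]
    bands: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.bands) != N_BANDS:
            raise ValueError(f"item {int(self.item)}: need {N_BANDS} bands, got {len(self.bands)}")
        if not self.probes:
            raise ValueError(f"item {int(self.item)}: no probe questions")
        for b, band in enumerate(self.bands):
            if not band:
                raise ValueError(f"item {int(self.item)}: band {b} is empty")


Lexicon = Mapping[MadrsItem, PhraseBank]


def token_lexicon() -> Lexicon:
    """Synthetic-token lexicon: severity markers ``sev0``-``sev6`` plus filler.

    Every utterance template in band ``b`` contains the marker ``sev{b}``,
    so the band of an emitted phrase can be recovered exactly with
    :data:`BAND_MARKER_RE` — convenient for signal-recovery checks.
    """
    banks = {}
    for item in MadrsItem:
        probes = tuple(f"probe item{int(item)} q{j}" for j in range(2))
        bands = tuple(
            tuple(
                f"sev{b} item{int(item)} fill{j} pad{(b + j) % 5}"
                for j in range(3)
            )
            for b in range(N_BANDS)
        )
        banks[item] = PhraseBank(item=item, probes=probes, bands=bands)
    return banks


_GERMAN_PROBES = {
    MadrsItem.REPORTED_SADNESS: ["Wie war Ihre Stimmung in der letzten Woche?"],
    MadrsItem.INNER_TENSION: ["Haben Sie sich in letzter Zeit angespannt oder unruhig gefühlt?"],
    MadrsItem.SLEEP_DISTURBANCES: ["Wie haben Sie in der letzten Woche geschlafen?"],
    MadrsItem.LOSS_OF_APPETITE: ["Wie war Ihr Appetit in den letzten Tagen?"],
    MadrsItem.DIFFICULTIES_CONCENTRATING: ["Können Sie sich zurzeit gut konzentrieren?"],
    MadrsItem.LASSITUDE: ["Fällt es Ihnen schwer, alltägliche Dinge anzugehen?"],
    MadrsItem.EMOTIONAL_NUMBNESS: ["Können Sie Freude oder Interesse empfinden wie früher?"],
    MadrsItem.PESSIMISTIC_THOUGHTS: ["Wie sehen Sie sich selbst und Ihre Zukunft?"],
    MadrsItem.SUICIDAL_IDEATIONS: ["Hatten Sie Gedanken, dass das Leben nicht mehr lebenswert sei?"],
}

_GERMAN_COMPLAINTS = {
    MadrsItem.REPORTED_SADNESS: "traurig und niedergeschlagen",
    MadrsItem.INNER_TENSION: "innerlich angespannt und nervös",
    MadrsItem.SLEEP_DISTURBANCES: "schlecht und unruhig geschlafen",
    MadrsItem.LOSS_OF_APPETITE: "ohne Appetit beim Essen",
    MadrsItem.DIFFICULTIES_CONCENTRATING: "unkonzentriert beim Lesen und Arbeiten",
    MadrsItem.LASSITUDE: "müde und ohne Antrieb",
    MadrsItem.EMOTIONAL_NUMBNESS: "innerlich leer und gefühllos",
    MadrsItem.PESSIMISTIC_THOUGHTS: "voller Selbstvorwürfe und Schwarzmalerei",
    MadrsItem.SUICIDAL_IDEATIONS: "von dunklen Gedanken geplagt",
}

# Severity-graded intensity frames, band 0 (none) to band 6 (most severe).
_GERMAN_FRAMES = [
    ("Eigentlich gar nicht, ich war überhaupt nicht {c}.", "Nein, damit hatte ich keine Probleme."),
    ("Nur ganz selten war ich ein wenig {c}.", "Kaum, höchstens einen kurzen Moment."),
    ("Ab und zu war ich etwas {c}.", "Gelegentlich schon, aber es ging vorbei."),
    ("Ich war öfter {c}, mehrmals in der Woche.", "Es kam schon regelmässig vor."),
    ("Ich war häufig {c}, fast jeden Tag.", "Das hat mich fast täglich beschäftigt."),
    ("Ich war sehr oft {c}, es hat mich stark belastet.", "Es war die meiste Zeit so und sehr belastend."),
    ("Ich war ständig {c}, es war kaum auszuhalten.", "Es war ununterbrochen da, schlimmer geht es kaum."),
]


def german_lexicon() -> Lexicon:
    """Small German-flavored lexicon for readable demo corpora."""
    banks = {}
    for item in MadrsItem:
        complaint = _GERMAN_COMPLAINTS[item]
        bands = tuple(
            tuple(frame.format(c=complaint) for frame in frames)
            for frames in _GERMAN_FRAMES
        )
        banks[item] = PhraseBank(
            item=item, probes=tuple(_GERMAN_PROBES[item]), bands=bands
        )
    return banks


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from YAML or JSON: ``{item_id: {probes, bands}}``."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    banks = {}
    for raw_id, entry in data.items():
        item = MadrsItem(int(raw_id))
        banks[item] = PhraseBank(
            item=item,
            probes=tuple(entry["probes"]),
            bands=tuple(tuple(b) for b in entry["bands"]),
        )
    missing = [int(i) for i in MadrsItem if i not in banks]
    if missing:
        raise ValueError(f"lexicon is missing phrase banks for items {missing}")
    return banks


def builtin_lexicon(name: str) -> Lexicon:
    """Resolve a built-in lexicon by name (``"token"`` or ``"german"``)."""
    if name == "token":
        return token_lexicon()
    if name == "german":
        return german_lexicon()
    raise ValueError(f"unknown built-in lexicon {name!r}")
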