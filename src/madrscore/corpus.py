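"""Data model and I/O for item-level MADRS interview segments.

The Montgomery-Åsberg Depression Rating Scale (MADRS) is a structured
clinical interview with ten symptom items, each rated 0 ("no symptoms")
to 6 ("most severe symptoms").  This package models the nine *verbal*
items (1-9); item 0, "apparent sadness", is rated from non-verbal cues
(posture, mimics) and is deliberately unrepresentable here.

A corpus is an ordered collection of :class:`ItemSample` records, each
pairing one item's dialog segment (probe question plus the patient's
free-form answer) with its clinician-assigned integer score.  The
canonical on-disk format is JSONL (one sample per line, UTF-8); CSV is
supported as a convenience dialect with dialog newlines escaped as
``\\n`` so that records stay one physical line each.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "MadrsItem",
    "ItemSample",
    "Corpus",
    "BalanceReport",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "score_distribution",
    "check_balance",
    "SCORES",
]

#: Valid integer severity scores for every item.
SCORES = tuple(range(7))


class MadrsItem(enum.IntEnum):
    """The nine verbal MADRS items, numbered 1-9 as in the instrument.

    Item 0 ("apparent sadness") cannot be constructed: its rating depends
    on body language and facial expression, not on the dialog text.
    """

    REPORTED_SADNESS = 1
    INNER_TENSION = 2
    SLEEP_DISTURBANCES = 3
    LOSS_OF_APPETITE = 4
    DIFFICULTIES_CONCENTRATING = 5
    LASSITUDE = 6
    EMOTIONAL_NUMBNESS = 7
    PESSIMISTIC_THOUGHTS = 8
    SUICIDAL_IDEATIONS = 9

    @property
    def label(self) -> str:
        """Human-readable item name, e.g. ``"inner tension"``."""
        return self.name.replace("_", " ").lower()


class CorpusValidationError(ValueError):
    """A corpus record violated the schema (bad field, range, duplicate)."""


_SOURCES = ("real", "synthetic")


@dataclass(frozen=True)
class ItemSample:
    """One MADRS item's dialog segment with its clinician score.

    Parameters
    ----------
    interview_id
        Opaque identifier of the interview the segment came from.
    item
        Which of the nine verbal MADRS items the segment covers.
    dialog
        Plain text of the segment: probe question and the patient's
        narrative answer, possibly multi-line.
    score
        Integer severity 0-6 assigned by the rater.
    source
        ``"real"`` for patient transcripts, ``"synthetic"`` for
        generated interviews.
    subject_id
        Optional subject identifier.  Repeat interviews of one subject
        are distinct interview_ids and are *not* grouped in any split;
        subject_id is carried only as metadata.
    """

    interview_id: str
    item: MadrsItem
    dialog: str
    score: int
    source: str = "synthetic"
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "item", MadrsItem(self.item))
        if not isinstance(self.score, int) or isinstance(self.score, bool):
            raise CorpusValidationError(f"score must be an integer, got {self.score!r}")
        if not 0 <= self.score <= 6:
            raise CorpusValidationError(f"score {self.score} outside the 0-6 range")
        if not self.dialog:
            raise CorpusValidationError("dialog text is empty")
        if self.source not in _SOURCES:
            raise CorpusValidationError(
                f"source must be one of {_SOURCES}, got {self.source!r}"
            )


@dataclass(frozen=True)
class Corpus:
    """Ordered, validated collection of :class:`ItemSample` records.

    Every ``(interview_id, item)`` pair appears at most once.
    """

    samples: tuple[ItemSample, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        seen: set[tuple[str, int]] = set()
        for i, s in enumerate(self.samples):
            key = (s.interview_id, int(s.item))
            if key in seen:
                raise CorpusValidationError(
                    f"record {i}: duplicate (interview_id, item) pair {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[ItemSample]:
        return iter(self.samples)

    def __getitem__(self, idx: int) -> ItemSample:
        return self.samples[idx]

    def subset(self, indices: Sequence[int]) -> "Corpus":
        return Corpus(tuple(self.samples[i] for i in indices))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per sample."""
        return pd.DataFrame(
            {
                "interview_id": [s.interview_id for s in self.samples],
                "subject_id": [s.subject_id for s in self.samples],
                "item": [int(s.item) for s in self.samples],
                "dialog": [s.dialog for s in self.samples],
                "score": [s.score for s in self.samples],
                "source": [s.source for s in self.samples],
            }
        )


_FIELDS = ("interview_id", "subject_id", "item", "dialog", "score", "source")


def _sample_from_record(record: dict, index: int) -> ItemSample:
    for name in ("item", "dialog", "score", "source"):
        if record.get(name) is None:
            raise CorpusValidationError(f"record {index}: missing field {name!r}")
        if record[name] == "" and name != "dialog":  # empty dialog gets its own error
            raise CorpusValidationError(f"record {index}: missing field {name!r}")
    try:
        item = MadrsItem(int(record["item"]))
    except ValueError as exc:
        raise CorpusValidationError(f"record {index}: field 'item': {exc}") from exc
    try:
        score = int(record["score"])
    except (TypeError, ValueError) as exc:
        raise CorpusValidationError(f"record {index}: field 'score': {exc}") from exc
    try:
        return ItemSample(
            interview_id=str(record.get("interview_id", f"rec-{index}")),
            subject_id=record.get("subject_id") or None,
            item=item,
            dialog=record["dialog"],
            score=score,
            source=record["source"],
        )
    except CorpusValidationError as exc:
        raise CorpusValidationError(f"record {index}: {exc}") from exc


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unknown corpus format {fmt!r}")
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a corpus from a JSONL or CSV file.

    The format is inferred from the suffix when not given (``.csv`` →
    CSV, anything else → JSONL).  Malformed records raise
    :class:`CorpusValidationError` naming the record index and field.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    samples: list[ItemSample] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusValidationError(f"record {i}: invalid JSON: {exc}") from exc
                samples.append(_sample_from_record(record, i))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader):
                if row.get("dialog") is not None:
                    row = dict(row)
                    row["dialog"] = row["dialog"].replace("\\n", "\n")
                samples.append(_sample_from_record(row, i))
    return Corpus(tuple(samples))


def write_corpus(corpus: Corpus, path: str | Path, format: Optional[str] = None) -> None:
    """Write a corpus to JSONL (canonical) or CSV (newlines escaped)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for s in corpus:
                record = {
                    "interview_id": s.interview_id,
                    "subject_id": s.subject_id,
                    "item": int(s.item),
                    "dialog": s.dialog,
                    "score": s.score,
                    "source": s.source,
                }
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            writer.writeheader()
            for s in corpus:
                writer.writerow(
                    {
                        "interview_id": s.interview_id,
                        "subject_id": s.subject_id or "",
                        "item": int(s.item),
                        "dialog": s.dialog.replace("\n", "\\n"),
                        "score": s.score,
                        "source": s.source,
                    }
                )


def score_distribution(corpus: Corpus) -> pd.DataFrame:
    """Count samples per (item, score) cell.

    Returns a 9x7 integer DataFrame indexed by item id 1-9 with columns
    0-6; zeros are kept so the grid shape is always the same.  Counts
    sum to ``len(corpus)``.
    """
    table = pd.DataFrame(
        0, index=[int(i) for i in MadrsItem], columns=list(SCORES), dtype=int
    )
    table.index.name = "item"
    table.columns.name = "score"
    for s in corpus:
        table.loc[int(s.item), s.score] += 1
    return table


@dataclass(frozen=True)
class BalanceReport:
    """Result of a minimum-count balance check over the 9x7 score grid."""

    ok: bool
    min_per_cell: int
    deficient: tuple[tuple[int, int, int], ...]  # (item, score, count)

    def __bool__(self) -> bool:
        return self.ok


def check_balance(corpus: Corpus, min_per_cell: int) -> BalanceReport:
    """Check that every (item, score) cell has at least ``min_per_cell`` samples.

    Mirrors the study-design constraint of a minimum number of interviews
    per score and item used to de-bias the severity distribution.
    """
    if min_per_cell < 0:
        raise ValueError("min_per_cell must be non-negative")
    dist = score_distribution(corpus)
    deficient = [
        (item, score, int(dist.loc[item, score]))
        for item in dist.index
        for score in dist.columns
        if dist.loc[item, score] < min_per_cell
    ]
    return BalanceReport(ok=not deficient, min_per_cell=min_per_cell, deficient=tuple(deficient))
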