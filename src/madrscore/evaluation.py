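"""Scoring metrics, baselines, confusion matrices and report tables.

Conventions
-----------
* Predictions are raw reals.  For accuracies they are rounded
  half-away-from-zero and clamped to the 0-6 score range
  (:func:`round_and_clamp`); MAE is computed on the *raw* predictions,
  the information-preserving reading of "average absolute deviation
  between predicted and true score".
* *Strict* accuracy counts exact rounded matches; *flexible* accuracy
  tolerates a ±1 deviation, reflecting the rater variability that is
  clinically accepted for MADRS item scores.
* Confusion matrices are 7x7 (true score on rows, rounded prediction on
  columns).  In flexible mode, predictions within ±1 of the truth are
  relocated to the diagonal; the strict matrix is always the lossless
  source of both accuracies.
* Report tables aggregate across folds with the unweighted mean (macro)
  and report per-item rows plus a Total row that is the unweighted mean
  of the nine per-item values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, ItemSample, MadrsItem

__all__ = [
    "ScoredPrediction",
    "ConfusionMatrix",
    "round_and_clamp",
    "score_predictions",
    "mae",
    "accuracy",
    "confusion",
    "baseline_mean_predictor",
    "baseline_predictions",
    "error_reduction",
    "per_item_fold_metrics",
    "aggregate_report",
    "format_report",
    "corpus_similarity",
]

N_SCORES = 7


def round_and_clamp(raw) -> np.ndarray | int:
    """Round half away from zero, then clamp into the 0-6 score range.

    Severity scales conventionally round midpoints up (2.5 → 3); the
    rule is centralized here so every accuracy and confusion count uses
    the same convention.  Non-finite input is rejected.
    """
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("round_and_clamp requires finite input")
    rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    clamped = np.clip(rounded, 0, 6).astype(int)
    return int(clamped) if np.isscalar(raw) or arr.ndim == 0 else clamped


@dataclass(frozen=True)
class ScoredPrediction:
    """One prediction: raw value, its rounded score, truth, item, fold."""

    raw: float
    true_score: int
    item: MadrsItem
    fold: int = 0

    @property
    def rounded(self) -> int:
        return round_and_clamp(self.raw)


def score_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Add a ``rounded`` column to a predictions table.

    Expects columns ``interview_id, item, score, raw_prediction, fold``
    as emitted by :func:`madrscore.training.run_cv`.
    """
    out = predictions.copy()
    out["rounded"] = round_and_clamp(out["raw_prediction"].to_numpy())
    return out


def _as_arrays(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("metric of an empty prediction set is undefined")
    return a, b


def mae(raw_predictions, true_scores) -> float:
    """Mean absolute error on raw (continuous) predictions."""
    raw, true = _as_arrays(raw_predictions, true_scores)
    return float(np.mean(np.abs(raw - true)))


def accuracy(rounded_predictions, true_scores, tolerance: int = 0) -> float:
    """Fraction of rounded predictions within ``tolerance`` of the truth.

    ``tolerance=0`` is the strict criterion, ``tolerance=1`` the
    flexible (±1) criterion.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    pred, true = _as_arrays(rounded_predictions, true_scores)
    return float(np.mean(np.abs(pred - true) <= tolerance))


@dataclass(frozen=True)
class ConfusionMatrix:
    """7x7 score confusion counts (rows: true, columns: predicted)."""

    counts: np.ndarray
    mode: str  # "strict" | "flexible"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (N_SCORES, N_SCORES):
            raise ValueError("confusion matrix must be 7x7")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def diagonal_fraction(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def band_fraction(self, tolerance: int = 1) -> float:
        """Mass within ``tolerance`` of the diagonal."""
        i, j = np.indices(self.counts.shape)
        return float(self.counts[np.abs(i - j) <= tolerance].sum() / self.total)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=range(N_SCORES), columns=range(N_SCORES))
        df.index.name = "true"
        df.columns.name = "predicted"
        return df


def confusion(rounded_predictions, true_scores, mode: str = "strict") -> ConfusionMatrix:
    """Build a score confusion matrix.

    Strict mode counts each prediction at (true, rounded).  Flexible
    mode relocates every off-by-one prediction to (true, true), so its
    diagonal equals the ±1 band of the strict matrix.
    """
    if mode not in ("strict", "flexible"):
        raise ValueError("mode must be 'strict' or 'flexible'")
    pred, true = _as_arrays(rounded_predictions, true_scores)
    pred = pred.astype(int)
    true = true.astype(int)
    counts = np.zeros((N_SCORES, N_SCORES), dtype=int)
    for t, p in zip(true, pred):
        if mode == "flexible" and abs(t - p) <= 1:
            counts[t, t] += 1
        else:
            counts[t, p] += 1
    return ConfusionMatrix(counts=counts, mode=mode)


def baseline_mean_predictor(
    train_samples: Iterable[ItemSample], item: MadrsItem
) -> float:
    """Constant per-item predictor: the mean training score of the item.

    A language-free lower performance bound — the error a model would
    make by relying on the score distribution alone.
    """
    scores = [s.score for s in train_samples if s.item == MadrsItem(item)]
    if not scores:
        raise ValueError(f"no training samples for item {int(item)}")
    return float(np.mean(scores))


def baseline_predictions(
    train_samples: Sequence[ItemSample], eval_samples: Sequence[ItemSample]
) -> np.ndarray:
    """Per-item mean-regression predictions for an evaluation set."""
    means = {
        int(item): baseline_mean_predictor(train_samples, item)
        for item in sorted({s.item for s in eval_samples})
    }
    return np.array([means[int(s.item)] for s in eval_samples])


def error_reduction(errors_base: int, errors_finetuned: int) -> float:
    """Percent decrease in error counts relative to the base model:
    ``(base - finetuned) / base * 100``.
    """
    if errors_base < 1:
        raise ValueError("error_reduction is undefined for a base error count of 0")
    if errors_finetuned < 0:
        raise ValueError("error counts must be non-negative")
    return (errors_base - errors_finetuned) / errors_base * 100.0


def per_item_fold_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """MAE, strict and flexible accuracy per (item, fold).

    Input: the out-of-fold predictions table (columns ``item, score,
    raw_prediction, fold``).  MAE uses raw predictions; accuracies use
    rounded ones.
    """
    scored = score_predictions(predictions)
    rows = []
    for (item, fold), grp in scored.groupby(["item", "fold"]):
        raw = grp["raw_prediction"].to_numpy()
        true = grp["score"].to_numpy()
        rounded = grp["rounded"].to_numpy()
        rows.append(
            dict(
                item=int(item),
                fold=int(fold),
                mae=mae(raw, true),
                strict_accuracy=accuracy(rounded, true, tolerance=0),
                flexible_accuracy=accuracy(rounded, true, tolerance=1),
            )
        )
    return pd.DataFrame(rows)


_METRIC_COLUMNS = ("mae", "strict_accuracy", "flexible_accuracy")


def aggregate_report(
    per_item_metrics: pd.DataFrame, metrics: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-item mean (± std across folds) table with a Total row.

    ``per_item_metrics`` needs an ``item`` column plus any subset of
    ``mae``, ``strict_accuracy``, ``flexible_accuracy`` (and optionally
    a ``fold`` column, over which means and stds are taken).  All nine
    items must be present.  The Total row is the unweighted mean of the
    nine per-item means — the macro average used in the published
    report tables.
    """
    present = sorted(set(per_item_metrics["item"]))
    expected = [int(i) for i in MadrsItem]
    if present != expected:
        missing = sorted(set(expected) - set(present))
        raise ValueError(f"metrics missing for items {missing}")
    cols = [c for c in (metrics or _METRIC_COLUMNS) if c in per_item_metrics.columns]
    if not cols:
        raise ValueError("no known metric columns present")
    rows = []
    for item in expected:
        grp = per_item_metrics[per_item_metrics["item"] == item]
        row: dict = {"item": item, "item_label": MadrsItem(item).label}
        for c in cols:
            row[c] = float(grp[c].mean())
            row[c + "_std"] = float(grp[c].std(ddof=1)) if len(grp) > 1 else float("nan")
        rows.append(row)
    total: dict = {"item": 0, "item_label": "total"}
    for c in cols:
        total[c] = float(np.mean([r[c] for r in rows]))
        total[c + "_std"] = float("nan")
    rows.append(total)
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Printable view: MAE to 2 decimals, accuracies to whole percent."""
    out = report.copy()
    for c in out.columns:
        if c.startswith("mae"):
            out[c] = out[c].round(2)
        elif c.endswith("accuracy") or c.endswith("accuracy_std"):
            out[c] = (out[c] * 100).round(0)
    return out


def corpus_similarity(corpus_a: Corpus, corpus_b: Corpus, model, tokenizer) -> float:
    """Cosine similarity of two corpora's mean pooled embeddings.

    Each sample is embedded by mask-weighted mean pooling of the
    encoder's final hidden states; corpora are summarized by the mean
    of their sample embeddings.  Used to compare synthetic against real
    interview text under a common encoder.
    """
    va = _corpus_embedding(corpus_a, model, tokenizer)
    vb = _corpus_embedding(corpus_b, model, tokenizer)
    denom = np.linalg.norm(va) * np.linalg.norm(vb)
    if denom == 0:
        raise ValueError("degenerate (all-zero) corpus embedding")
    return float(np.dot(va, vb) / denom)


def _corpus_embedding(corpus: Corpus, model, tokenizer, batch_size: int = 64) -> np.ndarray:
    from .model import make_batch  # late import to keep module layering simple

    if len(corpus) == 0:
        raise ValueError("cannot embed an empty corpus")
    vecs = []
    samples = list(corpus)
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        batch = make_batch(chunk, tokenizer, model.spec)
        h = model.encode(batch.token_ids, batch.mask)  # (B, L, H)
        w = batch.mask[:, :, None]
        pooled = (h * w).sum(axis=1) / w.sum(axis=1)
        vecs.append(pooled)
    return np.concatenate(vecs).mean(axis=0)
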