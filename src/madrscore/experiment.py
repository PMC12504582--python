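"""End-to-end experiment orchestration: fine-tuned vs. baselines.

Ties the corpus, model, training and evaluation modules together into
the full study protocol: stratified k-fold cross-validation of the
fine-tuned regressor, the per-item mean-regression baseline computed on
each training fold, and the zero-shot benchmark (untuned encoder with
fresh heads) evaluated on each validation fold — followed by report
tables, pooled confusion matrices and the error-reduction summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .corpus import Corpus, MadrsItem
from .evaluation import (
    ConfusionMatrix,
    accuracy,
    aggregate_report,
    baseline_mean_predictor,
    confusion,
    error_reduction,
    per_item_fold_metrics,
    round_and_clamp,
    score_predictions,
)
from .model import EncoderSpec, MultiHeadRegressor, Tokenizer, make_zero_shot_model
from .training import (
    CVResult,
    FoldPlan,
    TrainingConfig,
    make_fold_plan,
    predict_samples,
    run_cv,
    stratified_kfold,
)

__all__ = ["TrainEvalResult", "run_train_eval", "error_counts", "error_reduction_summary"]

MODEL_NAMES = ("finetuned", "baseline", "zero_shot")


def error_counts(predictions: pd.DataFrame) -> dict[str, int]:
    """Total strict and flexible error counts of a prediction table."""
    scored = score_predictions(predictions)
    diff = (scored["rounded"] - scored["score"]).abs()
    return {"strict": int((diff > 0).sum()), "flexible": int((diff > 1).sum())}


def error_reduction_summary(
    base_predictions: pd.DataFrame, finetuned_predictions: pd.DataFrame
) -> dict[str, float]:
    """Percent error reduction of fine-tuning vs. the base model, both criteria."""
    base = error_counts(base_predictions)
    fine = error_counts(finetuned_predictions)
    return {
        mode: error_reduction(base[mode], fine[mode])
        for mode in ("strict", "flexible")
        if base[mode] >= 1
    }


@dataclass
class TrainEvalResult:
    """All artifacts of one train-and-evaluate experiment."""

    predictions: dict[str, pd.DataFrame]  # model name -> out-of-fold predictions
    metrics: dict[str, pd.DataFrame]  # model name -> per (item, fold) metrics
    reports: dict[str, pd.DataFrame]  # model name -> per-item report with Total row
    confusions: dict[tuple[str, int, str], ConfusionMatrix]  # (model, item, mode)
    error_reductions: dict[str, float]  # criterion -> percent, fine-tuned vs zero-shot
    histories: list[pd.DataFrame]
    plan: FoldPlan

    def report(self, model: str = "finetuned") -> pd.DataFrame:
        return self.reports[model]


def _pooled_confusions(predictions: pd.DataFrame) -> dict[tuple[int, str], ConfusionMatrix]:
    """Per-item confusion matrices pooled over all validation folds."""
    scored = score_predictions(predictions)
    out = {}
    for item, grp in scored.groupby("item"):
        for mode in ("strict", "flexible"):
            out[(int(item), mode)] = confusion(
                grp["rounded"].to_numpy(), grp["score"].to_numpy(), mode=mode
            )
    return out


def run_train_eval(
    corpus: Corpus,
    tokenizer: Tokenizer,
    spec: EncoderSpec,
    training_config: TrainingConfig,
    k: int = 5,
    fold_seed: Optional[int] = None,
    model_factory: Optional[Callable[[int], MultiHeadRegressor]] = None,
) -> TrainEvalResult:
    """Run the full cross-validated comparison on one corpus.

    Returns out-of-fold predictions and per-item reports for the
    fine-tuned model, the per-item mean-regression baseline and the
    zero-shot benchmark, plus pooled per-item confusion matrices and
    the strict/flexible error-reduction of fine-tuning relative to the
    zero-shot model.
    """
    present = {int(s.item) for s in corpus}
    missing = sorted(set(int(i) for i in MadrsItem) - present)
    if missing:
        raise ValueError(f"corpus has no samples for items {missing}")
    if fold_seed is None:
        fold_seed = training_config.seed
    if model_factory is None:
        model_factory = lambda seed: MultiHeadRegressor(spec, seed=seed)
    plan = make_fold_plan(corpus, k=k, seed=fold_seed)

    cv = run_cv(corpus, model_factory, training_config, plan, tokenizer)
    predictions = {"finetuned": cv.predictions}

    baseline_rows = []
    zero_rows = []
    for fold, (train_idx, val_idx) in enumerate(stratified_kfold(corpus, plan)):
        train_set = [corpus[i] for i in train_idx]
        val_set = [corpus[i] for i in val_idx]
        means = {
            item: baseline_mean_predictor(train_set, MadrsItem(item))
            for item in sorted(present)
        }
        zs_model = make_zero_shot_model(spec, seed=training_config.seed + fold)
        zs_raw = predict_samples(zs_model, val_set, tokenizer)
        for s, z in zip(val_set, zs_raw):
            baseline_rows.append(
                dict(interview_id=s.interview_id, item=int(s.item), score=s.score,
                     raw_prediction=means[int(s.item)], fold=fold)
            )
            zero_rows.append(
                dict(interview_id=s.interview_id, item=int(s.item), score=s.score,
                     raw_prediction=float(z), fold=fold)
            )
    predictions["baseline"] = pd.DataFrame(baseline_rows)
    predictions["zero_shot"] = pd.DataFrame(zero_rows)

    metrics = {name: per_item_fold_metrics(df) for name, df in predictions.items()}
    reports = {name: aggregate_report(m) for name, m in metrics.items()}
    confusions = {
        (name, item, mode): cm
        for name, df in predictions.items()
        for (item, mode), cm in _pooled_confusions(df).items()
    }
    reductions = error_reduction_summary(predictions["zero_shot"], predictions["finetuned"])
    return TrainEvalResult(
        predictions=predictions,
        metrics=metrics,
        reports=reports,
        confusions=confusions,
        error_reductions=reductions,
        histories=cv.histories,
        plan=plan,
    )
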