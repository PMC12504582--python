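"""Reference per-item results of a full-scale MADRS scoring model.

These are the published per-item evaluation results of a full-scale
fine-tuned German clinical model on this task (65 patient interviews
plus 61 synthetic interviews; 1,242 item-level samples; fivefold
cross-validation).  They serve as worked-example inputs for the
report-aggregation machinery and as qualitative anchors for the
synthetic-data experiments: the package does not and cannot regenerate
them, since the underlying patient data is private.

Values: mean MADRS score per item, baseline (mean-regression) MAE,
fine-tuned MAE, and strict/flexible accuracies (in percent) of the
fine-tuned and untuned base models, as printed in the original report
(MAE to one decimal, accuracies to whole percent).
"""

from __future__ import annotations

import pandas as pd

from .corpus import MadrsItem

__all__ = [
    "reference_table1",
    "reference_table2",
    "OVERALL_ERROR_REDUCTION_FLEXIBLE",
    "OVERALL_ERROR_REDUCTION_STRICT",
]

# item, mean score, baseline MAE, fine-tuned MAE
_TABLE1 = [
    (MadrsItem.REPORTED_SADNESS, 3.0, 1.7, 0.9),
    (MadrsItem.INNER_TENSION, 3.0, 1.5, 0.7),
    (MadrsItem.SLEEP_DISTURBANCES, 2.9, 1.7, 0.9),
    (MadrsItem.LOSS_OF_APPETITE, 2.8, 1.8, 0.8),
    (MadrsItem.DIFFICULTIES_CONCENTRATING, 2.9, 1.7, 0.8),
    (MadrsItem.LASSITUDE, 2.8, 1.8, 0.8),
    (MadrsItem.EMOTIONAL_NUMBNESS, 2.8, 1.8, 1.0),
    (MadrsItem.PESSIMISTIC_THOUGHTS, 2.9, 1.6, 0.8),
    (MadrsItem.SUICIDAL_IDEATIONS, 2.9, 1.7, 0.8),
]

# item, fine-tuned flexible %, fine-tuned strict %, base flexible %, base strict %
_TABLE2 = [
    (MadrsItem.REPORTED_SADNESS, 80, 40, 29, 14),
    (MadrsItem.INNER_TENSION, 88, 49, 25, 12),
    (MadrsItem.SLEEP_DISTURBANCES, 82, 44, 30, 17),
    (MadrsItem.LOSS_OF_APPETITE, 79, 43, 33, 20),
    (MadrsItem.DIFFICULTIES_CONCENTRATING, 83, 40, 31, 15),
    (MadrsItem.LASSITUDE, 86, 46, 31, 19),
    (MadrsItem.EMOTIONAL_NUMBNESS, 80, 35, 33, 20),
    (MadrsItem.PESSIMISTIC_THOUGHTS, 85, 41, 26, 14),
    (MadrsItem.SUICIDAL_IDEATIONS, 83, 44, 32, 17),
]

#: Published overall error reductions of fine-tuning vs. the untuned base
#: model, under the flexible (±1) and strict criteria, in percent.
OVERALL_ERROR_REDUCTION_FLEXIBLE = 75.38
OVERALL_ERROR_REDUCTION_STRICT = 30.29


def reference_table1() -> pd.DataFrame:
    """Per-item mean score and MAE of baseline vs. fine-tuned model."""
    return pd.DataFrame(
        [
            dict(item=int(i), item_label=i.label, mean_score=m,
                 baseline_mae=b, finetuned_mae=f)
            for i, m, b, f in _TABLE1
        ]
    )


def reference_table2() -> pd.DataFrame:
    """Per-item strict/flexible accuracies (%) of fine-tuned vs. base model."""
    return pd.DataFrame(
        [
            dict(item=int(i), item_label=i.label,
                 finetuned_flexible=ff, finetuned_strict=fs,
                 base_flexible=bf, base_strict=bs)
            for i, ff, fs, bf, bs in _TABLE2
        ]
    )
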