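"""Cross-validated fine-tuning with baseline and zero-shot comparison.

Fine-tunes the tiny transformer regressor on a balanced synthetic
corpus (strong planted signal) under 5-fold stratified cross-validation
and prints the per-item report table — MAE, strict and flexible (±1)
accuracy — for the fine-tuned model next to the mean-regression
baseline and the untuned zero-shot benchmark, plus the error-reduction
summary.  Runs in well under a minute on one CPU.
"""

from madrscore import (
    EncoderSpec,
    GeneratorConfig,
    Tokenizer,
    TrainingConfig,
    format_report,
    generate_balanced_corpus,
    token_lexicon,
)
from madrscore.experiment import run_train_eval

lexicon = token_lexicon()
corpus = generate_balanced_corpus(
    GeneratorConfig(counts=15, signal_strength=1.0, noise_prob=0.0, seed=1, lexicon=lexicon)
)
tokenizer = Tokenizer.from_lexicon(lexicon)
spec = EncoderSpec.tiny(tokenizer.vocab_size)

result = run_train_eval(corpus, tokenizer, spec, TrainingConfig.desk_scale(seed=1), k=5)

for name in ("finetuned", "baseline", "zero_shot"):
    print(f"\n=== {name} ===")
    print(format_report(result.reports[name]).to_string(index=False))

print("\nerror reduction of fine-tuning vs zero-shot benchmark:")
for mode, pct in result.error_reductions.items():
    print(f"  {mode}: {pct:.2f}%")

# With a perfect planted signal the fine-tuned model drives MAE near 0
# and flexible accuracy to ~100%, while the baseline sits at MAE 12/7
# (~1.71) and the zero-shot model at ~14%/29% (the mass of labels 0 and
# {0,1} on a balanced score distribution).
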