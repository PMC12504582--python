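"""Prefix-subset learning curve of flexible accuracy vs training fraction.

For each of 5 outer folds, shuffles the 80% training pool once and
trains on growing prefixes (5%, 20%, 50%, 80% of the full dataset),
always evaluating on the same fixed 20% validation fold.  Prints the
mean flexible accuracy (± SEM across folds) per fraction: the curve
rises steeply and then plateaus once the signal is learned.
"""

from madrscore import (
    EncoderSpec,
    GeneratorConfig,
    LearningCurveConfig,
    MultiHeadRegressor,
    Tokenizer,
    TrainingConfig,
    generate_balanced_corpus,
    run_learning_curve,
    token_lexicon,
)

lexicon = token_lexicon()
corpus = generate_balanced_corpus(
    GeneratorConfig(counts=15, signal_strength=1.0, noise_prob=0.0, seed=2, lexicon=lexicon)
)
tokenizer = Tokenizer.from_lexicon(lexicon)
spec = EncoderSpec.tiny(tokenizer.vocab_size)

result = run_learning_curve(
    corpus,
    LearningCurveConfig(fractions=(0.05, 0.20, 0.50, 0.80), k=5, seed=2),
    TrainingConfig.desk_scale(seed=2),
    lambda seed: MultiHeadRegressor(spec, seed=seed),
    tokenizer,
)

print("mean flexible accuracy across items, per training fraction:")
print(result.overall().to_string(index=False))
print("\nper-item curve with SEM across the 5 folds:")
print(result.aggregate().to_string(index=False))

# Accuracy at 5% of the data is near chance-with-tolerance; by 50-80%
# it saturates — the rise-then-plateau shape expected when a model
# learns an unambiguous lexical severity signal.
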