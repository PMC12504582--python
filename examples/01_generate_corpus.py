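"""Generate a balanced synthetic interview corpus and inspect its balance.

Builds a corpus with 15 samples per (item, score) cell — nine MADRS
items x seven severity scores = 945 segments — with a perfect planted
severity signal, then prints the score-distribution grid and the
balance check.  A German-flavored sample dialog is shown at the end.
"""

from madrscore import (
    GeneratorConfig,
    check_balance,
    generate_balanced_corpus,
    german_lexicon,
    score_distribution,
)

config = GeneratorConfig(counts=15, signal_strength=1.0, noise_prob=0.0, seed=42)
corpus = generate_balanced_corpus(config)

print(f"corpus size: {len(corpus)} item-level samples")
print("\nscore distribution (rows: item 1-9, columns: score 0-6):")
print(score_distribution(corpus))

report = check_balance(corpus, min_per_cell=15)
print(f"\nbalance check at >=15 per cell: {'PASS' if report.ok else 'FAIL'}")

# the same generator with the readable German lexicon
demo = GeneratorConfig(counts=1, seed=42, lexicon=german_lexicon())
sample = generate_balanced_corpus(demo)[16]  # item 3 (sleep), score 2
print(f"\nexample dialog (item {int(sample.item)} '{sample.item.label}', "
      f"score {sample.score}):\n{sample.dialog}")

# Every cell printing 15 means the generator hit the requested balance
# exactly; the dialog shows the probe-question + patient-answer format.
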