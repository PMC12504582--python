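# Methods

## Problem and scope

`madrscore` predicts per-item MADRS severity scores (integers 0-6) from
the text of item-specific interview segments. Each sample is one item's
dialog — the clinician's probe question plus the patient's free-form
answer — treated independently of the rest of the interview. The nine
verbal items (ids 1-9) are modeled; item 0 ("apparent sadness") depends
on posture and facial expression and is unrepresentable in the data
model. Repeat interviews of one subject are deliberately *not* grouped
during fold assignment (they are distinct clinical states weeks apart);
`subject_id` is carried as metadata so a grouped-split mode could be
added later.

## Model

A shared bidirectional transformer encoder with nine per-item linear
regression heads on the final-layer summary-token state (position 0,
taken raw, before any pooler nonlinearity). A sample is routed through
exactly the head of its item; the loss for a mixed-item batch is the
plain mean of per-sample squared errors, each sample scored by its own
head. Predictions are unbounded reals; rounding and clamping happen
only at evaluation.

The encoder is size-parameterized (`EncoderSpec`). The working default
for experiments and tests is deliberately tiny — 2 post-LayerNorm
blocks, hidden 64, 4 attention heads, GELU feed-forward of width 256,
maximum 64 tokens — so a full 5-fold experiment runs in ~20 s on one
CPU core. A full-size pretrained checkpoint can be used instead via
`pretrained_ref` (encoder weights are loaded; heads are always freshly
initialized). All weights initialize from N(0, 0.02²); with fresh heads
this makes raw zero-shot predictions concentrate near zero, so the
untuned benchmark rounds essentially everything to score 0 — the
qualitative signature of an unadapted encoder on this task. The exact
initialization that produces that behavior is not uniquely determined;
zero-centered small-variance is the conventional choice and reproduces
it robustly.

The forward/backward passes are written in NumPy (`madrscore.nn`,
`madrscore.model`) with explicit caches; gradient correctness is pinned
by finite-difference tests. There is no dropout: desk-scale runs are
exactly deterministic given the seed, and regularization at this scale
comes from weight decay and early stopping.

## Training recipe

`TrainingConfig` defaults are the published fine-tuning recipe: AdamW
(runtime-default betas/epsilon), learning rate 2e-5, decoupled weight
decay 0.01, batch size 4, up to 15 epochs, per-step global gradient
norm clipped at 0.5, 500 warmup steps then linear decay, early stopping
with patience 5 on validation loss, best-epoch checkpoint restored.

Two scale adaptations, both logged when they trigger:

* **Warmup cap.** 500 warmup steps can exceed an entire desk-scale run;
  when the scheduled horizon is under 5,000 steps, warmup is capped at
  10% of it, preserving the schedule's shape.
* **Decay horizon.** Linear decay targets `max_epochs ×
  steps_per_epoch` even if early stopping halts sooner (the horizon is
  not otherwise specified by the recipe).

`TrainingConfig.desk_scale()` (learning rate 1e-3, 3 epochs) is the
preset for training the tiny encoder *from scratch*: 2e-5 is an
adaptation rate for a pretrained full-size model and moves a randomly
initialized 2-layer network only ~1% of the distance it needs in three
epochs. 1e-3 is the conventional Adam rate for small transformers
trained from scratch and was fixed as part of the reduced-scale study
design.

Weight decay is applied to weight matrices only — biases, LayerNorm
parameters and the regression heads are excluded. Excluding the heads
preserves a structural property worth testing: a gradient step on
samples of item *i* leaves heads *j ≠ i* bit-identical (decay would
otherwise shrink untouched heads).

Training is a function of the training *set* and the seed, not of the
order samples are passed in: `train()` canonicalizes sample order
before its seeded epoch shuffles. This is what makes the largest
learning-curve fraction reproduce the plain CV result exactly.

## Cross-validation

Stratified shuffled k-fold (default k=5) on the joint (item, score)
key, so each fold mirrors both the item and the severity distribution;
when some (item, score) stratum holds fewer than k samples the plan
falls back to item-only stratification with a warning. One global seed
derives per-fold seeds as `seed + fold` for model initialization and
batch shuffling; a fresh model is initialized per fold and weights are
never shared across folds.

## Learning curves

Per outer fold, the 80% training pool is shuffled once with the fold
seed; fraction *f* of the *entire* dataset takes the first ⌊f·N⌋
samples of that shuffle, so smaller fractions are strict prefixes of
larger ones, and every model is evaluated on the fold's fixed 20%
validation set. Reported per item: mean flexible accuracy across folds
with SEM = std/√k. Whether the full-scale protocol re-stratified each
fraction is unknowable from its description; the prefix-of-one-shuffle
reading is implemented as stated.

## Evaluation conventions

* **Rounding**: half away from zero (2.5 → 3), then clamp to 0-6 —
  severity scales conventionally round midpoints up; centralized in
  `round_and_clamp`.
* **MAE on raw predictions**: the regression target is continuous, and
  raw-MAE is the stricter, information-preserving reading of "average
  absolute deviation"; accuracies use rounded predictions.
* **Flexible confusion matrices** relocate off-by-one mass to the
  diagonal (the strict matrix remains the lossless source; flexible
  accuracy equals its ±1 band mass, which is cross-checked in tests).
* **Aggregation**: macro — unweighted mean of per-fold accuracies, then
  the Total row as the unweighted mean of the nine per-item values;
  printable reports round MAE to 2 decimals and accuracies to whole
  percent.
* **Baseline** ("mean regression"): the per-item mean score of the
  training fold. On a balanced 0-6 distribution its MAE is exactly
  12/7 ≈ 1.71 and its flexible accuracy 3/7 ≈ 43% — balancing the
  corpus makes this floor *easier*, which is the right mental baseline
  when reading synthetic-corpus results.
* **Error reduction**: `(E_base − E_fine)/E_base × 100` on total error
  counts (strict: any miss; flexible: misses beyond ±1); undefined when
  the base model makes no errors.
* **Corpus similarity**: cosine between the mean mask-weighted
  pooled-embedding vectors of two corpora under a common encoder, for
  real-vs-synthetic comparisons.

## Synthetic corpus generator

The generator stands in for both private patient transcripts and
hand-curated synthetic interviews. It emulates the corpus *structure* —
item-segmented dialogs, a probe question followed by patient turns, any
requested count per (item, score) cell (default 15 per cell, the
minimum-per-score-and-item balancing constraint of the full-scale
study; 945 samples) — and plants a lexical severity signal with an
explicit noise model. Per patient utterance: with probability
`noise_prob` a uniformly random *wrong* severity band; otherwise band
`b = round(score·s + u·(1−s))` with `s = signal_strength` and `u` a
uniform integer on {0..6}. `s=1` makes the band equal the score; `s=0`
makes it exactly uniform and score-independent (the integer-`u` choice
keeps the zero-signal distribution uniform, which a continuous uniform
would not). The linear band-mixing model is this package's own
construction — the full-scale study states only the balancing goal.

Two phrase banks ship: a synthetic token vocabulary (`sev0`…`sev6`
markers plus filler) used by the test suite, so correctness checks are
language-independent and emitted bands are mechanically recoverable;
and a small German-flavored lexicon for readable demos. Generation is
deterministic given (config, seed), with one child stream per cell, and
synthetic ids follow `syn-{item}-{score}-{index}`.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: natural-language variability and ambiguity,
dialect, ASR noise, within-interview context, rater disagreement, and
any correlation structure across items of one interview. Results on
the planted-signal corpus bound pipeline correctness, not clinical
performance.

## Reference results

`madrscore.reference` carries the published per-item results of the
full-scale model (per-item mean scores, baseline and fine-tuned MAE,
strict/flexible accuracies, overall error reductions 75.38%/30.29%).
They are inputs for worked examples and aggregation checks only — the
underlying patient data is private, so those numbers cannot be
regenerated here; the package's experiments reproduce the *mechanics*
(aggregation arithmetic, metric definitions, qualitative zero-shot
collapse, rise-then-plateau learning curves) at desk scale. The
printed overall error reductions depend on unpublished per-item error
counts and are therefore anchored qualitatively (fine-tuned ≫ base)
rather than numerically.

## Problem sizes used in tests and the acceptance script

Balanced 945-sample corpora (15 per cell), tiny encoder, 5-fold CV at
3 epochs, learning-curve grid {0.05, 0.20, 0.50, 0.80}; chosen so the
full suite and the acceptance run each complete in a few minutes on a
single CPU core while keeping every stratum large enough for exact
(item, score) stratification. The isotonic-residual tolerance for
learning-curve monotonicity is 0.05 on the item-averaged curve (0.10
per item), absorbing fold-level sampling noise at 189-sample validation
folds.

## Known limitations

* No dropout or mixed precision; single-device only.
* Word-level tokenizer (lowercased, vocabulary from the phrase banks)
  rather than subword; adequate for the built-in lexicons, not for
  open-vocabulary German text.
* The mean-regression baseline and sign-test comparisons assume
  reasonably balanced evaluation sets; heavily skewed corpora make the
  baseline floor item-dependent.
* Folds are not grouped by subject (by design, mirroring the full-scale
  protocol); a grouped mode would be needed to quantify the resulting
  optimism on real repeat-interview data.
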