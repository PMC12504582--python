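"""Fold plans, the training loop (schedule, early stopping), CV, learning curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import madrscore.training as tr
from madrscore import (
    GeneratorConfig,
    LearningCurveConfig,
    MultiHeadRegressor,
    TrainingConfig,
    generate_balanced_corpus,
    make_fold_plan,
    run_cv,
    run_learning_curve,
    stratified_kfold,
    token_lexicon,
    train,
)
from madrscore.evaluation import accuracy, baseline_predictions, mae, per_item_fold_metrics, round_and_clamp
from madrscore.training import (
    effective_warmup,
    learning_curve_subsets,
    predict_samples,
)
from conftest import make_flat_corpus


class TestFoldPlan:
    def test_balanced_945_gives_189_per_fold_3_per_cell(self, balanced_corpus_945):
        plan = make_fold_plan(balanced_corpus_945, k=5, seed=0)
        folds = stratified_kfold(balanced_corpus_945, plan)
        for train_idx, val_idx in folds:
            assert len(val_idx) == 189 and len(train_idx) == 756
            cells = {}
            for i in val_idx:
                s = balanced_corpus_945[i]
                cells[(int(s.item), s.score)] = cells.get((int(s.item), s.score), 0) + 1
            assert set(cells.values()) == {3}  # 15 per cell / 5 folds

    def test_folds_partition_the_corpus(self, small_corpus):
        plan = make_fold_plan(small_corpus, k=3, seed=1)
        folds = stratified_kfold(small_corpus, plan)
        all_val = np.concatenate([v for _, v in folds])
        assert sorted(all_val) == list(range(len(small_corpus)))
        for train_idx, val_idx in folds:
            assert not set(train_idx) & set(val_idx)

    def test_k_of_one_rejected(self, small_corpus):
        with pytest.raises(ValueError, match="k"):
            make_fold_plan(small_corpus, k=1)

    def test_k_exceeding_corpus_rejected(self):
        c = make_flat_corpus(n_per_cell=1, scores=[0])  # 9 samples
        with pytest.raises(ValueError):
            make_fold_plan(c, k=10)

    def test_same_seed_identical_assignments(self, small_corpus):
        a = make_fold_plan(small_corpus, k=3, seed=3)
        b = make_fold_plan(small_corpus, k=3, seed=3)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_sparse_strata_fall_back_to_item_stratification(self):
        c = make_flat_corpus(n_per_cell=1)  # one sample per (item, score)
        with pytest.warns(UserWarning, match="item-only"):
            plan = make_fold_plan(c, k=3, seed=0)
        assert plan.stratification == "item"
        # per item, fold sizes still differ by at most one
        items = np.array([int(s.item) for s in c])
        for item in range(1, 10):
            sizes = [np.sum((plan.assignments == f) & (items == item)) for f in range(3)]
            assert max(sizes) - min(sizes) <= 1


class TestSchedule:
    def test_warmup_capped_at_ten_percent_for_short_runs(self):
        assert effective_warmup(500, 567) == 56
        assert effective_warmup(500, 10000) == 500
        assert effective_warmup(30, 1000) == 30

    def test_lr_multiplier_ramps_then_decays_to_zero(self):
        total, warm = 100, 10
        ramp = [tr.nn.lr_multiplier(s, total, warm) for s in range(1, 11)]
        assert ramp == pytest.approx([s / 10 for s in range(1, 11)])
        assert tr.nn.lr_multiplier(100, total, warm) == 0.0
        mids = [tr.nn.lr_multiplier(s, total, warm) for s in (11, 50, 99)]
        assert mids == sorted(mids, reverse=True)


class TestEarlyStopping:
    """Patience arithmetic, exercised with scripted validation losses."""

    @pytest.fixture()
    def tiny_train(self, tokenizer, tiny_spec, small_corpus):
        model = MultiHeadRegressor(tiny_spec, seed=0)
        samples = list(small_corpus)[:8]
        return model, samples[:6], samples[6:]

    def _run(self, monkeypatch, tiny_train, tokenizer, losses, max_epochs=15, patience=5):
        it = iter(losses)
        monkeypatch.setattr(tr, "evaluate_loss", lambda *a, **k: next(it))
        model, train_set, val_set = tiny_train
        cfg = TrainingConfig(learning_rate=1e-4, max_epochs=max_epochs,
                             early_stopping_patience=patience, seed=0)
        return train(model, train_set, val_set, cfg, tokenizer)

    def test_constant_loss_stops_after_one_plus_patience_epochs(
        self, monkeypatch, tiny_train, tokenizer
    ):
        res = self._run(monkeypatch, tiny_train, tokenizer, [1.0] * 15)
        assert res.stopped_epoch == 6 and res.best_epoch == 1

    def test_strictly_improving_loss_runs_all_epochs(self, monkeypatch, tiny_train, tokenizer):
        res = self._run(monkeypatch, tiny_train, tokenizer,
                        [1.0 / (e + 1) for e in range(15)])
        assert res.stopped_epoch == 15 and res.best_epoch == 15

    def test_best_epoch_checkpoint_restored(self, monkeypatch, tiny_train, tokenizer):
        res = self._run(monkeypatch, tiny_train, tokenizer,
                        [3.0, 1.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        assert res.best_epoch == 2 and res.stopped_epoch == 7

    def test_empty_sets_rejected(self, tokenizer, tiny_spec, small_corpus):
        model = MultiHeadRegressor(tiny_spec, seed=0)
        with pytest.raises(ValueError):
            train(model, [], list(small_corpus)[:2], TrainingConfig(seed=0), tokenizer)


class TestTrainingLearnsSignal:
    def test_beats_baseline_on_separable_corpus(self, tokenizer, tiny_spec, lexicon):
        """Tiny encoder on a perfectly separable corpus beats the mean predictor."""
        corpus = generate_balanced_corpus(
            GeneratorConfig(counts=4, signal_strength=1.0, noise_prob=0.0, seed=5,
                            lexicon=lexicon)
        )
        plan = make_fold_plan(corpus, k=4, seed=0)
        train_idx, val_idx = stratified_kfold(corpus, plan)[0]
        train_set = [corpus[i] for i in train_idx]
        val_set = [corpus[i] for i in val_idx]
        model = MultiHeadRegressor(tiny_spec, seed=0)
        res = train(model, train_set, val_set, TrainingConfig.desk_scale(seed=0), tokenizer)
        raw = predict_samples(res.model, val_set, tokenizer)
        true = np.array([s.score for s in val_set])
        base = baseline_predictions(train_set, val_set)
        assert mae(raw, true) < mae(base, true)

    def test_divergence_detected(self, tokenizer, tiny_spec, small_corpus):
        model = MultiHeadRegressor(tiny_spec, seed=0)
        model.params["head_W"][:] = np.inf
        with np.errstate(invalid="ignore"), pytest.raises(tr.TrainingDivergedError):
            train(model, list(small_corpus)[:4], list(small_corpus)[4:6],
                  TrainingConfig.desk_scale(seed=0), tokenizer)


@pytest.fixture(scope="module")
def cv_setup(tokenizer, tiny_spec, lexicon):
    corpus = generate_balanced_corpus(
        GeneratorConfig(counts=2, signal_strength=1.0, seed=2, lexicon=lexicon)
    )
    cfg = TrainingConfig.desk_scale(seed=0, max_epochs=1)
    plan = make_fold_plan(corpus, k=2, seed=0)
    factory = lambda seed: MultiHeadRegressor(tiny_spec, seed=seed)
    return corpus, cfg, plan, factory


class TestRunCV:
    def test_every_sample_predicted_exactly_once(self, cv_setup, tokenizer):
        corpus, cfg, plan, factory = cv_setup
        cv = run_cv(corpus, factory, cfg, plan, tokenizer)
        keys = list(zip(cv.predictions["interview_id"], cv.predictions["item"]))
        assert len(keys) == len(corpus) and len(set(keys)) == len(corpus)

    def test_rerun_with_same_seeds_identical(self, cv_setup, tokenizer):
        corpus, cfg, plan, factory = cv_setup
        a = run_cv(corpus, factory, cfg, plan, tokenizer)
        b = run_cv(corpus, factory, cfg, plan, tokenizer)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_fold_metric_dispersion_reported_as_std(self, cv_setup, tokenizer):
        corpus, cfg, plan, factory = cv_setup
        cv = run_cv(corpus, factory, cfg, plan, tokenizer)
        metrics = per_item_fold_metrics(cv.predictions)
        assert set(metrics["fold"]) == {0, 1}
        from madrscore.evaluation import aggregate_report
        rep = aggregate_report(metrics)
        item1 = metrics[metrics["item"] == 1]["mae"]
        assert rep.loc[rep["item"] == 1, "mae_std"].iloc[0] == pytest.approx(
            item1.std(ddof=1)
        )


class TestLearningCurve:
    def test_prefix_subsets_sizes_and_nesting(self):
        rng = np.random.default_rng(0)
        pool = np.arange(800)
        subsets = learning_curve_subsets(pool, [0.05, 0.80], 1000, rng)
        assert len(subsets[0.05]) == 50 and len(subsets[0.80]) == 800
        np.testing.assert_array_equal(subsets[0.80][:50], subsets[0.05])

    def test_zero_size_fraction_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="empty subset"):
            subsets = learning_curve_subsets(np.arange(8), [0.05, 0.5], 10, rng)
        assert list(subsets) == [0.5]

    def test_fraction_config_validation(self):
        with pytest.raises(ValueError):
            LearningCurveConfig(fractions=(0.9,))
        with pytest.raises(ValueError):
            LearningCurveConfig(fractions=(0.5, 0.2))

    def test_sem_is_std_over_sqrt_k(self, tokenizer, tiny_spec, lexicon):
        corpus = generate_balanced_corpus(
            GeneratorConfig(counts=2, signal_strength=1.0, seed=2, lexicon=lexicon)
        )
        lc = LearningCurveConfig(fractions=(0.5,), k=2, seed=0)
        cfg = TrainingConfig.desk_scale(seed=0, max_epochs=1)
        res = run_learning_curve(corpus, lc, cfg,
                                 lambda s: MultiHeadRegressor(tiny_spec, seed=s), tokenizer)
        agg = res.aggregate()
        pts = res.points
        row = agg[(agg["item"] == 1) & (agg["fraction"] == 0.5)].iloc[0]
        vals = pts[(pts["item"] == 1) & (pts["fraction"] == 0.5)]["flexible_accuracy"]
        assert row["sem"] == pytest.approx(vals.std(ddof=1) / np.sqrt(2))

    def test_largest_fraction_reproduces_plain_cv_fold(self, tokenizer, tiny_spec, lexicon):
        """With k=2 the 0.5 fraction is the whole training pool, so the point
        must coincide with the plain CV result for that fold."""
        corpus = generate_balanced_corpus(
            GeneratorConfig(counts=2, signal_strength=1.0, seed=2, lexicon=lexicon)
        )
        cfg = TrainingConfig.desk_scale(seed=0, max_epochs=1)
        factory = lambda s: MultiHeadRegressor(tiny_spec, seed=s)
        plan = make_fold_plan(corpus, k=2, seed=0)
        cv = run_cv(corpus, factory, cfg, plan, tokenizer)
        cv_metrics = per_item_fold_metrics(cv.predictions)
        lc = LearningCurveConfig(fractions=(0.5,), k=2, seed=0)
        res = run_learning_curve(corpus, lc, cfg, factory, tokenizer)
        merged = res.points.merge(cv_metrics, on=["item", "fold"])
        np.testing.assert_allclose(
            merged["flexible_accuracy_x"], merged["flexible_accuracy_y"]
        )
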