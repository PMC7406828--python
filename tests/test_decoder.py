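"""Decoder architecture, fold plans, cropped training and statistics."""

import numpy as np
import pandas as pd
import pytest

from expmse_decode.decoder import (Fold, build_model, compare_kinds,
                                   make_inter_folds, make_intra_folds,
                                   predict_trial, spec_for_kind,
                                   train_model, AccuracyReport)
from expmse_decode.errors import ConfigError
from expmse_decode.features import CropSet
from expmse_decode.nn import EarlyStopper


def toy_crop_set(n_tasks=4, trials_per_task=14, crops_per_trial=8,
                 shape=(6, 30), separation=3.0, seed=0, n_subjects=1):
    """Separable-by-construction crops: one mean pattern per task."""
    rng = np.random.default_rng(seed)
    tasks = [f"T{i}" for i in range(n_tasks)]
    patterns = {t: separation * rng.normal(size=shape) for t in tasks}
    data, labels, trial_ids, meta = [], [], [], []
    key = 0
    for subj in range(n_subjects):
        for task in tasks:
            for trial in range(trials_per_task):
                for _ in range(crops_per_trial):
                    data.append(patterns[task]
                                + rng.normal(size=shape))
                    labels.append(task)
                    trial_ids.append(key)
                meta.append((key, subj, 2, task, trial + 2))
                key += 1
    meta = pd.DataFrame(meta, columns=["trial_key", "subject", "session",
                                       "task", "trial"])
    meta["label"] = meta["task"]
    return CropSet("expmse", np.array(data), np.array(labels),
                   np.array(trial_ids), meta)


class TestModel:
    def test_output_is_probability_vector(self):
        spec = spec_for_kind("expmse", (68, 30), 4)
        model = build_model(spec)
        x = np.random.default_rng(0).normal(size=(5, 68, 30))
        p = model.predict_proba(x)
        assert p.shape == (5, 4)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_bandpower_variant_accepts_68x3(self):
        spec = spec_for_kind("bandpower", (68, 3), 4)
        model = build_model(spec)
        x = np.random.default_rng(0).normal(size=(2, 68, 3))
        assert model.predict_proba(x).shape == (2, 4)

    def test_same_spec_and_seed_build_identical_models(self):
        spec = spec_for_kind("expmse", (6, 30), 4, seed=7)
        a, b = build_model(spec), build_model(spec)
        assert a.n_parameters == b.n_parameters
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_pool_larger_than_map_rejected(self):
        spec = spec_for_kind("expmse", (2, 30), 4)
        with pytest.raises(ConfigError):
            build_model(spec)


class TestIntraFolds:
    def test_14_trials_give_12_folds_with_433_groups(self):
        meta = toy_crop_set(trials_per_task=14).trial_meta
        plan = make_intra_folds(meta, seed=3)
        assert len(plan.folds) == 12
        for fold in plan.folds:
            assert not set(fold.train) & set(fold.test)
            assert not set(fold.train) & set(fold.val)
            assert not set(fold.val) & set(fold.test)
            union = set(fold.train) | set(fold.val) | set(fold.test)
            assert union == set(meta["trial_key"])

    def test_group_sizes_are_4433_per_task(self):
        meta = toy_crop_set(trials_per_task=14, n_tasks=1).trial_meta
        plan = make_intra_folds(meta, seed=0)
        groups = {tuple(f.test) for f in plan.folds}
        sizes = sorted(len(g) for g in groups)
        assert sizes == [3, 3, 4, 4]

    def test_too_few_trials_rejected(self):
        meta = toy_crop_set(trials_per_task=3).trial_meta
        with pytest.raises(ConfigError):
            make_intra_folds(meta, seed=0)


class TestInterFolds:
    def test_one_fold_per_subject(self):
        meta = toy_crop_set(trials_per_task=14, n_subjects=8).trial_meta
        plan = make_inter_folds(meta, seed=0)
        assert len(plan.folds) == 8
        for s, fold in zip(plan.held_out, plan.folds):
            test_subjects = set(
                meta.loc[meta.trial_key.isin(fold.test), "subject"])
            assert test_subjects == {s}
            # remaining subjects contribute 7 train + 7 val per task
            others = meta[meta.subject != s]
            for other in set(others.subject):
                for task in set(others.task):
                    keys = set(others.loc[(others.subject == other)
                                          & (others.task == task),
                                          "trial_key"])
                    assert len(keys & set(fold.train)) == 7
                    assert len(keys & set(fold.val)) == 7

    def test_fewer_than_three_subjects_rejected(self):
        meta = toy_crop_set(n_subjects=2).trial_meta
        with pytest.raises(ConfigError):
            make_inter_folds(meta, seed=0)


@pytest.fixture(scope="module")
def trained_toy():
    crop_set = toy_crop_set(trials_per_task=8, crops_per_trial=8,
                            shape=(6, 10), separation=2.0)
    plan = make_intra_folds(crop_set.trial_meta, seed=1)
    spec = spec_for_kind("expmse", (6, 10), 4, filters=(4, 8),
                         max_epochs=60, patience=15, seed=2)
    trained = train_model(crop_set, plan.folds[0], spec)
    return crop_set, plan, spec, trained


class TestTraining:
    def test_separable_fixture_trains_to_high_accuracy(self, trained_toy):
        crop_set, plan, _, trained = trained_toy
        fold = plan.folds[0]
        correct = sum(
            predict_trial(trained, crop_set, k).predicted_label
            == predict_trial(trained, crop_set, k).true_label
            for k in fold.train)
        assert correct / len(fold.train) > 0.9

    def test_prediction_probabilities_sum_to_one(self, trained_toy):
        crop_set, plan, _, trained = trained_toy
        pred = predict_trial(trained, crop_set, plan.folds[0].test[0])
        assert pred.mean_proba.sum() == pytest.approx(1.0, abs=1e-9)
        assert pred.predicted_label == trained.classes[
            int(np.argmax(pred.mean_proba))]

    def test_trial_prediction_matches_naive_averaging(self, trained_toy):
        crop_set, plan, _, trained = trained_toy
        key = plan.folds[0].test[0]
        idx = crop_set.crops_of_trial(key)
        probs = np.array([
            trained.predict_proba(crop_set.data[i: i + 1])[0]
            for i in idx])
        pred = predict_trial(trained, crop_set, key)
        np.testing.assert_allclose(pred.mean_proba, probs.mean(axis=0),
                                   atol=1e-12)

    def test_empty_train_set_rejected(self, trained_toy):
        crop_set, plan, spec, _ = trained_toy
        with pytest.raises(ConfigError):
            train_model(crop_set, Fold((), plan.folds[0].val,
                                       plan.folds[0].test), spec)

    def test_training_is_reproducible(self):
        crop_set = toy_crop_set(trials_per_task=4, crops_per_trial=4,
                                shape=(6, 10))
        plan = make_intra_folds(crop_set.trial_meta, seed=1)
        spec = spec_for_kind("expmse", (6, 10), 4, filters=(2, 4),
                             max_epochs=3, seed=5)
        t1 = train_model(crop_set, plan.folds[0], spec)
        t2 = train_model(crop_set, plan.folds[0], spec)
        for a, b in zip(t1.model.parameters(), t2.model.parameters()):
            np.testing.assert_array_equal(a, b)
        assert t1.history["train_loss"] == t2.history["train_loss"]


class TestEarlyStopping:
    def test_monotone_rise_after_epoch_5_halts_by_epoch_8(self):
        stopper = EarlyStopper(patience=3)
        losses = [1.0, 0.8, 0.6, 0.5, 0.45, 0.44, 0.5, 0.6, 0.7, 0.8, 0.9]
        stopped_at = None
        for epoch, loss in enumerate(losses):
            if stopper.update(loss, epoch):
                stopped_at = epoch
                break
        assert stopped_at == 8
        assert stopper.best_epoch == 5


class TestStatistics:
    def _report(self, acc):
        return AccuracyReport("expmse", "intra", list(acc),
                              pd.DataFrame(columns=["fold", "trial_key",
                                                    "true", "predicted"]))

    def test_identical_reports_give_p_one(self):
        r = self._report([70, 75, 80])
        assert compare_kinds(r, r) == 1.0

    def test_t_statistic_matches_hand_computation(self):
        a = self._report([79, 82, 75, 80, 78, 83, 77, 81])
        b = self._report([68, 70, 66, 71, 64, 72, 69, 67])
        p = compare_kinds(a, b)
        d = np.array(a.fold_accuracy) - np.array(b.fold_accuracy)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist
        p_hand = 2 * tdist.sf(abs(t), df=len(d) - 1)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_all_correct_is_100_percent(self):
        preds = pd.DataFrame({"fold": [0, 0], "trial_key": [1, 2],
                              "true": ["A", "B"],
                              "predicted": ["A", "B"]})
        r = AccuracyReport("expmse", "intra", [100.0], preds)
        assert r.overall_accuracy == 100.0

    def test_unpaired_reports_rejected(self):
        with pytest.raises(ConfigError):
            compare_kinds(self._report([1, 2]), self._report([1, 2, 3]))
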