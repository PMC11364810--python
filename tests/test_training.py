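"""Training protocols: stratified splitting, cross-entropy, model selection
bookkeeping, reproducibility, and leakage audits by trial fingerprinting."""

import hashlib
from dataclasses import replace

import numpy as np
import pytest

import ctnet.training as training_mod
from ctnet.model import ModelConfig, build_model
from ctnet.preprocess import AugmentConfig
from ctnet.synthetic import SynthConfig, generate_mi_trials, generate_subjects
from ctnet.training import (FitHistory, SplitError, TrainConfig,
                            cross_entropy, fit, run_loso,
                            run_subject_specific, split_train_val)

from conftest import tiny_model_cfg


def small_set(n_per_class=10, t=256, seed=0, n_classes=2):
    return generate_mi_trials(SynthConfig(n_per_class=n_per_class, C=3, T=t,
                                          n_classes=n_classes, seed=seed))


def fingerprints(ts) -> set:
    return {hashlib.sha1(ts.data[i].tobytes()).hexdigest()
            for i in range(ts.n_trials)}


class TestSplit:
    def test_stratified_70_30(self):
        ts = small_set(n_per_class=25, n_classes=4, t=64)   # 100 trials
        tr, va = split_train_val(ts, 0.30, seed=0)
        assert tr.n_trials == 70 and va.n_trials == 30
        for c in range(4):
            assert 7 <= len(va.class_indices(c)) <= 8

    def test_disjoint_union_preserves_input(self):
        ts = small_set(t=64)
        tr, va = split_train_val(ts, 0.3, seed=1)
        f_tr, f_va, f_all = fingerprints(tr), fingerprints(va), fingerprints(ts)
        assert not (f_tr & f_va)
        assert f_tr | f_va == f_all

    def test_seed_determinism(self):
        ts = small_set(t=64)
        a = split_train_val(ts, 0.3, seed=5)
        b = split_train_val(ts, 0.3, seed=5)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        c = split_train_val(ts, 0.3, seed=6)
        assert not np.array_equal(a[0].data, c[0].data)

    def test_zero_fraction_rejected(self):
        with pytest.raises(SplitError):
            split_train_val(small_set(t=64), 0.0, seed=0)

    def test_tiny_class_rejected(self):
        ts = small_set(n_per_class=1, t=64)
        with pytest.raises(SplitError, match="need >= 2"):
            split_train_val(ts, 0.3, seed=0)


class TestCrossEntropy:
    def test_perfect_predictions_give_zero_loss(self):
        y = np.eye(3)
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_over_four_classes_is_ln4(self):
        p = np.full((5, 4), 0.25)
        y = np.eye(4)[[0, 1, 2, 3, 0]]
        assert cross_entropy(p, y) == pytest.approx(np.log(4), abs=1e-12)

    def test_hand_worked_two_sample_case(self):
        p = np.array([[0.8, 0.2], [0.4, 0.6]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = -(np.log(0.8) + np.log(0.6)) / 2
        assert cross_entropy(p, y) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.366985, abs=1e-6)

    def test_zero_probability_clamped_finite(self):
        p = np.array([[1.0, 0.0]])
        y = np.array([[0.0, 1.0]])
        assert np.isfinite(cross_entropy(p, y))


class TestFit:
    def test_two_epoch_bookkeeping(self):
        ts = small_set(n_per_class=10, t=256)
        tr, va = split_train_val(ts, 0.3, seed=0)
        model = build_model(tiny_model_cfg(), seed=0)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=0, augment=None)
        _, hist = fit(model, tr, va, cfg)
        assert len(hist.train_loss) == len(hist.val_loss) == 2
        assert hist.selected_epoch in (0, 1)

    def test_selected_epoch_minimizes_validation_loss(self):
        ts = small_set(n_per_class=10, t=256, seed=3)
        tr, va = split_train_val(ts, 0.3, seed=0)
        model = build_model(tiny_model_cfg(), seed=1)
        cfg = TrainConfig(epochs=4, batch_size=8, seed=0, augment=None)
        _, hist = fit(model, tr, va, cfg)
        assert hist.val_loss[hist.selected_epoch] == min(hist.val_loss)

    def test_empty_validation_rejected(self):
        ts = small_set(t=64)
        model = build_model(tiny_model_cfg(T=64, Kc1=8, Kc2=4, P1=4, P2=2))
        with pytest.raises(ValueError):
            fit(model, ts, ts.subset([]), TrainConfig(epochs=1, augment=None))


class TestSubjectSpecific:
    def _pairs(self, n=2, seed=0):
        pairs = []
        for s in range(n):
            tr = small_set(n_per_class=6, t=256, seed=seed + s)
            te = small_set(n_per_class=4, t=256, seed=seed + 100 + s)
            tr.subject_id = te.subject_id = f"S{s:02d}"
            te.session_tag = "test"
            pairs.append((tr, te))
        return pairs

    def test_confusion_matrices_cover_test_sets(self):
        pairs = self._pairs()
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0,
                          augment=AugmentConfig(K=4, multiplier=1))
        results = run_subject_specific(pairs, tiny_model_cfg(), cfg)
        assert len(results) == 2
        for (tr, te), r in zip(pairs, results):
            assert r.confusion.sum() == te.n_trials
            assert r.subject_id == te.subject_id

    def test_identical_subjects_identical_results(self):
        pairs = self._pairs(1) * 2
        pairs = [(replace(a, subject_id="SX"), replace(b, subject_id="SX"))
                 for a, b in pairs]
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0, augment=None)
        r = run_subject_specific(pairs, tiny_model_cfg(), cfg)
        np.testing.assert_array_equal(r[0].confusion, r[1].confusion)

    def test_mismatched_subject_ids_rejected(self):
        (tr, te), = self._pairs(1)
        te = replace(te, subject_id="OTHER")
        with pytest.raises(ValueError, match="mismatch"):
            run_subject_specific([(tr, te)], tiny_model_cfg(),
                                 TrainConfig(epochs=1, augment=None))

    def test_empty_test_set_rejected(self):
        (tr, te), = self._pairs(1)
        te = te.subset([])
        with pytest.raises(ValueError, match="empty test set"):
            run_subject_specific([(tr, te)], tiny_model_cfg(),
                                 TrainConfig(epochs=1, augment=None))

    def test_end_to_end_run_is_reproducible(self):
        pairs = self._pairs(1)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=7,
                          augment=AugmentConfig(K=4, multiplier=1))
        a = run_subject_specific(pairs, tiny_model_cfg(), cfg)
        b = run_subject_specific(pairs, tiny_model_cfg(), cfg)
        np.testing.assert_array_equal(a[0].confusion, b[0].confusion)


class TestLeakageAudit:
    """Fingerprint audit: the held-out/test trials must never reach fit()."""

    def _capture_fit(self, monkeypatch):
        captured = []

        def stub(model, train, val, cfg):
            captured.append((train, val))
            return model, FitHistory([0.0], [0.0], [0.5], 0)

        monkeypatch.setattr(training_mod, "fit", stub)
        return captured

    def test_subject_specific_never_trains_on_test_trials(self, monkeypatch):
        captured = self._capture_fit(monkeypatch)
        tr = small_set(n_per_class=6, t=256, seed=0)
        te = small_set(n_per_class=4, t=256, seed=1)
        tr.subject_id = te.subject_id = "S00"
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0,
                          augment=AugmentConfig(K=4, multiplier=1))
        run_subject_specific([(tr, te)], tiny_model_cfg(), cfg)
        from ctnet.preprocess import zscore_trialset
        test_fp = fingerprints(zscore_trialset(te))
        for train, val in captured:
            assert not (fingerprints(train) & test_fp)
            assert not (fingerprints(val) & test_fp)

    def test_loso_pool_excludes_held_out_subject(self, monkeypatch):
        captured = self._capture_fit(monkeypatch)
        subs = generate_subjects(SynthConfig(n_per_class=4, T=256, seed=0), 3)
        run_loso(subs, tiny_model_cfg(),
                 TrainConfig(epochs=1, batch_size=8, augment=None))
        from ctnet.preprocess import zscore_trialset
        assert len(captured) == 3
        for held, (train, val) in enumerate(captured):
            held_fp = fingerprints(zscore_trialset(subs[held]))
            assert not (fingerprints(train) & held_fp)
            assert not (fingerprints(val) & held_fp)

    def test_validation_never_contains_artificial_trials(self, monkeypatch):
        # augmentation happens after the split, on the training part only
        captured = self._capture_fit(monkeypatch)
        tr = small_set(n_per_class=6, t=256, seed=0)
        te = small_set(n_per_class=4, t=256, seed=1)
        tr.subject_id = te.subject_id = "S00"
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0,
                          augment=AugmentConfig(K=4, multiplier=2))
        run_subject_specific([(tr, te)], tiny_model_cfg(), cfg)
        from ctnet.preprocess import zscore_trialset
        orig_fp = fingerprints(zscore_trialset(tr))
        (train, val), = captured
        assert fingerprints(val) <= orig_fp
        assert train.n_trials == (tr.n_trials - val.n_trials) * 3


class TestLoso:
    def test_single_subject_rejected(self):
        subs = generate_subjects(SynthConfig(n_per_class=4, T=256), 1)
        with pytest.raises(ValueError, match="2 subjects"):
            run_loso(subs, tiny_model_cfg(), TrainConfig(epochs=1, augment=None))

    def test_empty_subject_rejected(self):
        subs = generate_subjects(SynthConfig(n_per_class=4, T=256), 2)
        subs[1] = subs[1].subset([])
        with pytest.raises(ValueError, match="empty"):
            run_loso(subs, tiny_model_cfg(), TrainConfig(epochs=1, augment=None))

    def test_strong_effect_loso_mean_accuracy_at_least_080(self):
        # easy fixture: 4x band-power contrast shared across subjects
        subs = generate_subjects(SynthConfig(n_per_class=30, effect=3.0,
                                             seed=7), 3)
        cfg = TrainConfig(epochs=10, batch_size=64, seed=0,
                          augment=AugmentConfig(K=8, multiplier=1))
        results = run_loso(subs, ModelConfig.iv2b(), cfg)
        assert np.mean([r.accuracy for r in results]) >= 0.80

    def test_three_subjects_yield_three_results(self):
        subs = generate_subjects(SynthConfig(n_per_class=4, T=256, seed=2), 3)
        cfg = TrainConfig(epochs=1, batch_size=8, augment=None)
        results = run_loso(subs, tiny_model_cfg(), cfg)
        assert [r.subject_id for r in results] == ["S01", "S02", "S03"]
        for s, r in zip(subs, results):
            assert r.confusion.sum() == s.n_trials
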