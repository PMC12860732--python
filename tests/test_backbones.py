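"""Class weights, weighted losses, oversampling and the linear reference
backbone."""

import math
from collections import Counter

import numpy as np
import pytest

from softvote import backbones as bb
from softvote.corpus import MULTI_CLASS, MULTI_LABEL, LabelMatrix
from softvote.embeddings import HybridVectorizer, random_table
from softvote.folds import tri_split
from softvote.synth import GeneratorConfig, generate_corpus


def _ml(values):
    values = np.asarray(values)
    return LabelMatrix(MULTI_LABEL, [f"l{i}" for i in range(values.shape[1])], values)


def _mc(values, c):
    return LabelMatrix(MULTI_CLASS, [f"l{i}" for i in range(c)], np.asarray(values))


class TestClassWeights:
    def test_balanced_classes_give_unit_weights(self):
        labels = _mc([0] * 10 + [1] * 10, 2)
        assert np.allclose(bb.compute_class_weights(labels).w, [1.0, 1.0])

    def test_inverse_frequency_hand_case(self):
        labels = _mc([0] * 30 + [1] * 10, 2)
        assert np.allclose(bb.compute_class_weights(labels).w, [0.5, 1.5])

    def test_all_equal_multilabel(self):
        y = np.zeros((12, 3), dtype=int)
        y[:4, 0] = 1
        y[4:8, 1] = 1
        y[8:, 2] = 1
        w = bb.compute_class_weights(_ml(y)).w
        assert np.allclose(w, [1.0, 1.0, 1.0])
        assert w.mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_positive_class_is_an_error(self):
        y = np.zeros((5, 2), dtype=int)
        y[:, 0] = 1
        with pytest.raises(ValueError, match="zero training positives"):
            bb.compute_class_weights(_ml(y))


class TestLosses:
    def test_bce_ln2_anchor(self):
        w = bb.ClassWeights(np.array([1.0]))
        loss = bb.weighted_bce_loss(np.array([0.0]), np.array([1.0]), w)
        assert loss == pytest.approx(math.log(2), abs=1e-12)

    def test_bce_perfect_prediction_limit(self):
        w = bb.ClassWeights(np.ones(3))
        loss = bb.weighted_bce_loss(
            np.array([40.0, 40.0, 40.0]), np.array([1.0, 1.0, 1.0]), w
        )
        assert loss < 1e-9

    def test_bce_linear_in_weights(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=4)
        y = (rng.random(4) < 0.5).astype(float)
        w1 = bb.ClassWeights(rng.random(4) + 0.1)
        w2 = bb.ClassWeights(2 * w1.w)
        a = bb.weighted_bce_loss(z, y, w1)
        assert bb.weighted_bce_loss(z, y, w2) == pytest.approx(2 * a, rel=1e-12)

    def test_ce_ln4_anchor(self):
        w = bb.ClassWeights(np.ones(4))
        loss = bb.weighted_ce_loss(np.zeros(4), 0, w)
        assert loss == pytest.approx(math.log(4), abs=1e-12)

    def test_ce_shift_invariance_and_limit(self):
        w = bb.ClassWeights(np.ones(3))
        z = np.array([1.0, -2.0, 0.5])
        assert bb.weighted_ce_loss(z, 1, w) == pytest.approx(
            bb.weighted_ce_loss(z + 7.3, 1, w), rel=1e-12
        )
        assert bb.weighted_ce_loss(np.array([50.0, 0.0, 0.0]), 0, w) < 1e-9

    def test_losses_match_scalar_oracle_on_random_triples(self):
        # independent scalar evaluation with math.log, element by element
        rng = np.random.default_rng(42)
        for _ in range(50):
            c = int(rng.integers(1, 6))
            z = rng.normal(scale=3, size=c)
            y = (rng.random(c) < 0.5).astype(float)
            w = bb.ClassWeights(rng.random(c) + 0.1)
            expected = 0.0
            for j in range(c):
                p = 1.0 / (1.0 + math.exp(-z[j]))
                p = min(max(p, 1e-12), 1 - 1e-12)
                expected -= w.w[j] * (
                    y[j] * math.log(p) + (1 - y[j]) * math.log(1 - p)
                )
            expected /= c
            assert bb.weighted_bce_loss(z, y, w) == pytest.approx(
                expected, abs=1e-9
            )
            k = int(rng.integers(0, c))
            denom = sum(math.exp(zj - max(z)) for zj in z)
            pk = math.exp(z[k] - max(z)) / denom
            assert bb.weighted_ce_loss(z, k, w) == pytest.approx(
                -w.w[k] * math.log(min(max(pk, 1e-12), 1 - 1e-12)), abs=1e-9
            )


class TestOversampling:
    def test_multiclass_cap_rule(self):
        y = _mc([0] * 100 + [1] * 20, 2)
        idx = np.arange(120)
        out = bb.oversample_training_fold(idx, y, 0.5, seed=0)
        counts = Counter(np.asarray(y.values)[out])
        assert counts[0] == 100 and counts[1] == 50

    def test_balanced_fold_unchanged(self):
        y = _mc([0] * 30 + [1] * 30, 2)
        out = bb.oversample_training_fold(np.arange(60), y, 0.5, seed=0)
        assert sorted(out.tolist()) == list(range(60))

    def test_nested_sampling_submultiset(self):
        y = _mc([0] * 100 + [1] * 10 + [2] * 30, 3)
        idx = np.arange(140)
        small = Counter(bb.oversample_training_fold(idx, y, 0.25, seed=3).tolist())
        big = Counter(bb.oversample_training_fold(idx, y, 0.5, seed=3).tolist())
        assert all(big[k] >= v for k, v in small.items())

    def test_invalid_r_rejected(self):
        y = _mc([0, 1], 2)
        for r in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                bb.oversample_training_fold(np.arange(2), y, r, seed=0)

    def test_multilabel_rarest_first_reaches_target_or_budget(self):
        rng = np.random.default_rng(5)
        y = (rng.random((200, 4)) < [0.5, 0.2, 0.1, 0.05]).astype(int)
        y[0] = [1, 1, 1, 1]  # ensure every label has a positive
        labels = _ml(y)
        idx = np.arange(200)
        out = bb.oversample_training_fold(idx, labels, 0.5, seed=1)
        assert len(out) <= 2 * 200
        counts = labels.one_hot()[out].sum(axis=0)
        target = math.ceil(0.5 * counts.max())
        for c in range(4):
            assert counts[c] >= min(
                target, labels.one_hot()[idx].sum(axis=0)[c]
            ) or len(out) == 400


class TestTraining:
    def _fixture(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        # two separable labels over 10 features
        X = rng.normal(size=(n, 10))
        y = np.stack([(X[:, 0] > 0), (X[:, 1] > 0)], axis=1).astype(int)
        return X, _ml(y)

    def test_separable_set_reaches_high_train_f1(self):
        X, y = self._fixture()
        model = bb.train_reference_backbone(
            X, y, config=bb.TrainConfig(max_epochs=80, patience=80)
        )
        assert model._val_macro_f1(X, y) > 0.99

    def test_same_seed_identical_parameters(self):
        X, y = self._fixture()
        cfg = bb.TrainConfig(max_epochs=15, patience=15, seed=7)
        m1 = bb.train_reference_backbone(X, y, config=cfg)
        m2 = bb.train_reference_backbone(X, y, config=cfg)
        assert np.array_equal(m1.W, m2.W) and np.array_equal(m1.b, m2.b)

    def test_patience_one_with_flat_validation_stops_at_epoch_two(self):
        X, y = self._fixture()
        # validation labels all zero -> macro-F1 constant at 0
        val_X = X[:20]
        val_y = _ml(np.zeros((20, 2), dtype=int))
        model = bb.train_reference_backbone(
            X, y, config=bb.TrainConfig(max_epochs=30, patience=1),
            val_features=val_X, val_labels=val_y,
        )
        assert model.n_epochs_run == 2

    def test_multiclass_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 8))
        y = _mc(rng.integers(0, 3, size=120), 3)
        model = bb.train_reference_backbone(
            X, y, config=bb.TrainConfig(max_epochs=10, patience=10)
        )
        probs = model.predict_proba(X)
        assert np.abs(probs.values.sum(axis=1) - 1.0).max() < 1e-9

    def test_save_load_roundtrip(self, tmp_path):
        X, y = self._fixture()
        model = bb.train_reference_backbone(
            X, y, config=bb.TrainConfig(max_epochs=5, patience=5)
        )
        path = tmp_path / "model.json"
        model.save(path)
        back = bb.LinearBackbone.load(path)
        assert np.allclose(
            back.predict_proba(X).values, model.predict_proba(X).values
        )

    def test_nonfinite_features_rejected(self):
        X, y = self._fixture()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            bb.train_reference_backbone(X, y)


def test_class_weights_raise_minority_recall_at_half_threshold():
    """Inverse-frequency weighting raises minority-label recall at tau=0.5
    versus unit weights (mean over 10 seeds) on an imbalanced corpus with
    overlapping classes (weak planted signal, moderate L2)."""
    gains = []
    for seed in range(10):
        cfg = GeneratorConfig(
            n_docs=1500,
            n_labels=2,
            label_base_rates=(0.45, 0.05),
            signal_prob=0.3,
            lexicon_size_per_label=8,
            noise_vocab_size=300,
            seed=seed,
        )
        corpus, labels, _ = generate_corpus(cfg)
        vocab = sorted({t for d in corpus for t in d.tokens})
        vz = HybridVectorizer(
            random_table(vocab, 60, seed * 2 + 1),
            random_table(vocab, 60, seed * 2 + 2),
        )
        feats = bb.view_features(corpus, vz, None)
        fold = tri_split(labels, seed=seed).folds[0]
        train_cfg = bb.TrainConfig(seed=seed, max_epochs=40, patience=40, l2=0.01)
        weighted = bb.compute_class_weights(labels.subset(fold.train))
        recall = {}
        for tag, w in (("w", weighted), ("u", bb.ClassWeights.unit(2))):
            model = bb.train_reference_backbone(
                feats[fold.train], labels.subset(fold.train),
                weights=w, config=train_cfg,
            )
            p = model.predict_proba(feats[fold.test]).values[:, 1]
            y = labels.subset(fold.test).one_hot()[:, 1]
            recall[tag] = ((p >= 0.5) & (y == 1)).sum() / max((y == 1).sum(), 1)
        gains.append(recall["w"] - recall["u"])
    assert np.mean(gains) > 0
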