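"""Soft-voting fusion, threshold calibration, decision rules and the
ensemble-variance identity."""

import warnings

import numpy as np
import pytest

from softvote.backbones import ProbMatrix
from softvote.corpus import MULTI_CLASS, MULTI_LABEL, LabelMatrix
from softvote.fusion import (
    DEFAULT_GRID,
    FusionModel,
    calibrate_thresholds,
    compute_fusion_weights,
    decide_multiclass,
    decide_multilabel,
    decomposition_rhs,
    fuse_probabilities,
    variance_decomposition,
)


def _pm(values, mode=MULTI_LABEL):
    return ProbMatrix(np.asarray(values, dtype=float), mode)


class TestWeights:
    def test_equal_scores_half_half(self):
        assert np.allclose(compute_fusion_weights([0.8, 0.8]), [0.5, 0.5])

    def test_hand_normalization(self):
        assert np.allclose(compute_fusion_weights([0.6, 0.2]), [0.75, 0.25])

    def test_single_member(self):
        assert np.allclose(compute_fusion_weights([0.4]), [1.0])

    def test_all_zero_falls_back_to_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            w = compute_fusion_weights([0.0, 0.0, 0.0])
        assert np.allclose(w, [1 / 3] * 3)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_fusion_weights([0.5, 1.2])


class TestFuse:
    def test_identical_members_fixed_point(self):
        m = _pm([[0.2, 0.9], [0.4, 0.1]])
        fused = fuse_probabilities([m, m, m], [0.2, 0.5, 0.3])
        assert np.allclose(fused.values, m.values)

    def test_hand_weighted_mean(self):
        a = _pm([[0.9, 0.1]])
        b = _pm([[0.5, 0.5]])
        fused = fuse_probabilities([a, b], [0.75, 0.25])
        assert np.allclose(fused.values, [[0.8, 0.2]])

    def test_multiclass_rows_stay_on_simplex(self):
        rng = np.random.default_rng(0)
        members = []
        for _ in range(3):
            raw = rng.random((20, 4))
            members.append(_pm(raw / raw.sum(axis=1, keepdims=True), MULTI_CLASS))
        fused = fuse_probabilities(members, [0.5, 0.3, 0.2])
        assert np.abs(fused.values.sum(axis=1) - 1.0).max() < 1e-9

    def test_shape_mismatch_names_member(self):
        a = _pm(np.zeros((3, 2)))
        b = _pm(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="member 1"):
            fuse_probabilities([a, b], [0.5, 0.5])


def _labels_ml(values):
    values = np.asarray(values)
    return LabelMatrix(MULTI_LABEL, [f"l{i}" for i in range(values.shape[1])], values)


class TestCalibration:
    def test_default_grid_is_nine_point(self):
        assert DEFAULT_GRID == (0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70)

    def test_perfect_separation_ties_to_smallest_tau(self):
        probs = _pm([[0.95], [0.92], [0.08], [0.05]])
        y = _labels_ml([[1], [1], [0], [0]])
        taus = calibrate_thresholds(probs, y)
        assert taus[0] == pytest.approx(0.30)

    def test_matches_bruteforce_grid_scoring(self):
        probs = _pm(np.array([[0.65], [0.55], [0.45], [0.35], [0.25]]))
        y = _labels_ml([[1], [1], [1], [0], [0]])
        taus = calibrate_thresholds(probs, y)

        def f1_at(tau):
            pred = probs.values[:, 0] >= tau
            truth = y.values[:, 0].astype(bool)
            tp = (pred & truth).sum()
            fp = (pred & ~truth).sum()
            fn = (~pred & truth).sum()
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            return 2 * p * r / (p + r) if p + r else 0.0

        best = max(f1_at(t) for t in DEFAULT_GRID)
        assert f1_at(taus[0]) == pytest.approx(best)
        # tie rule: no smaller grid tau achieves the same F1
        for t in DEFAULT_GRID:
            if t < taus[0]:
                assert f1_at(t) < best

    def test_grid_optimality_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, c = 30, 3
            probs = _pm(rng.random((n, c)))
            y = _labels_ml((rng.random((n, c)) < 0.4).astype(int))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                taus = calibrate_thresholds(probs, y)
            for j in range(c):
                truth = y.values[:, j].astype(bool)
                if not truth.any():
                    continue

                def f1_at(tau):
                    pred = probs.values[:, j] >= tau
                    tp = (pred & truth).sum()
                    fp = (pred & ~truth).sum()
                    fn = (~pred & truth).sum()
                    p = tp / (tp + fp) if tp + fp else 0.0
                    r = tp / (tp + fn) if tp + fn else 0.0
                    return 2 * p * r / (p + r) if p + r else 0.0

                assert all(f1_at(t) <= f1_at(taus[j]) + 1e-12 for t in DEFAULT_GRID)

    def test_zero_positive_class_gets_midpoint_with_warning(self):
        probs = _pm(np.array([[0.2], [0.8]]))
        y = _labels_ml([[0], [0]])
        with pytest.warns(UserWarning):
            taus = calibrate_thresholds(probs, y)
        assert taus[0] == pytest.approx(0.50)


class TestDecisions:
    def test_threshold_is_inclusive(self):
        fused = _pm([[0.40, 0.39]])
        pred = decide_multilabel(fused, np.array([0.40, 0.40]))
        assert pred.tolist() == [[1, 0]]

    def test_all_zero_row_allowed(self):
        fused = _pm([[0.1, 0.1]])
        assert decide_multilabel(fused, np.array([0.5, 0.5])).tolist() == [[0, 0]]

    def test_lowering_tau_only_adds_positives(self):
        rng = np.random.default_rng(1)
        fused = _pm(rng.random((50, 4)))
        hi = decide_multilabel(fused, np.full(4, 0.6))
        lo = decide_multilabel(fused, np.full(4, 0.4))
        assert np.all(lo >= hi)

    def test_argmax_and_tie_rule(self):
        fused = _pm(
            [[0.1, 0.7, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]], MULTI_CLASS
        )
        pred = decide_multiclass(fused)
        assert pred.tolist() == [1, 0]


class TestVarianceIdentity:
    def test_single_member(self):
        m = _pm(np.array([[0.2], [0.6], [0.9]]))
        lhs, variances, cov = variance_decomposition([m], [1.0], 0)
        assert lhs == pytest.approx(float(m.values[:, 0].var()), abs=1e-12)

    def test_perfectly_correlated_members(self):
        m = _pm(np.array([[0.2], [0.6], [0.9]]))
        lhs, variances, cov = variance_decomposition([m, m], [0.5, 0.5], 0)
        assert lhs == pytest.approx(float(m.values[:, 0].var()), abs=1e-12)
        assert cov[0, 1] == pytest.approx(variances[0], abs=1e-12)

    def test_identity_on_random_members(self):
        rng = np.random.default_rng(2)
        members = [_pm(rng.random((50, 1))) for _ in range(4)]
        w = compute_fusion_weights(rng.random(4) * 0.5 + 0.2)
        lhs, _, cov = variance_decomposition(members, w, 0)
        assert lhs == pytest.approx(decomposition_rhs(w, cov), abs=1e-10)


def test_fusion_model_roundtrip_and_invariants(tmp_path):
    model = FusionModel(
        member_names=["a", "b"],
        weights=np.array([0.6, 0.4]),
        task_mode=MULTI_LABEL,
        thresholds=np.array([0.3, 0.55]),
    )
    path = tmp_path / "fusion.json"
    model.to_json(path)
    back = FusionModel.from_json(path)
    assert back.member_names == ["a", "b"]
    assert np.allclose(back.weights, model.weights)
    assert np.allclose(back.thresholds, model.thresholds)
    with pytest.raises(ValueError):
        FusionModel(["a"], np.array([0.9]), MULTI_LABEL)
    with pytest.raises(ValueError):
        FusionModel(
            ["a"], np.array([1.0]), MULTI_LABEL, thresholds=np.array([0.9])
        )


def test_weighted_fusion_not_worse_than_uniform_on_unequal_members():
    """With members of unequal quality, validation-weighted fusion's
    validation macro-F1 is >= uniform fusion's in the majority of 20
    seeded trials (directional property of the weighting rule)."""
    from softvote.metrics import macro_f1

    rng_master = np.random.default_rng(123)
    wins = 0
    for _ in range(20):
        seed = int(rng_master.integers(2**31))
        rng = np.random.default_rng(seed)
        n, c = 120, 4
        y = (rng.random((n, c)) < 0.35).astype(int)
        members, scores = [], []
        for noise in (0.15, 0.3, 0.45, 0.6):
            p = np.clip(y + rng.normal(0, noise, size=(n, c)), 0, 1)
            members.append(_pm(p))
            scores.append(macro_f1(y, (p >= 0.5).astype(int)))
        w = compute_fusion_weights(np.array(scores))
        uw = np.full(4, 0.25)
        f_w = macro_f1(y, (fuse_probabilities(members, w).values >= 0.5).astype(int))
        f_u = macro_f1(y, (fuse_probabilities(members, uw).values >= 0.5).astype(int))
        wins += f_w >= f_u
    assert wins > 10
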