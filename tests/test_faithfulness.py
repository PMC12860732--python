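"""Deletion-curve faithfulness, sufficiency/comprehensiveness, and
stability across explainer re-runs."""

import numpy as np
import pytest

from softvote.corpus import Document
from softvote.faithfulness import (
    DeletionCurve,
    apply_policy,
    auc_del,
    deletion_curve,
    kendall_stability,
    overlap_at_k,
    robustness_suite,
    sufficiency_comprehensiveness,
)
from softvote.lime import Explanation, ExplainerConfig, explain


def _doc(tokens, did="d"):
    return Document(did, " ".join(tokens), tuple(tokens))


def _expl(tokens, scores, c=0, k=None):
    scores = np.asarray(scores, dtype=float)
    ranked = sorted(range(len(scores)), key=lambda i: (-abs(scores[i]), i))
    k = len(scores) if k is None else k
    return Explanation(
        doc_id="d",
        class_index=c,
        tokens=tuple(tokens),
        scores=scores,
        intercept=0.0,
        top_positions=ranked[:k],
    )


class TestApplyPolicy:
    def test_empty_positions_leave_doc_unchanged(self):
        doc = _doc(["a", "b", "c"])
        for policy in ("mask", "delete", "unk"):
            out = apply_policy(doc, set(), policy)
            assert out.tokens == doc.tokens

    def test_delete_hand_splice(self):
        doc = _doc(["a", "b", "c", "d"])
        assert apply_policy(doc, {0, 2}, "delete").tokens == ("b", "d")

    def test_mask_preserves_length_delete_shrinks(self):
        doc = _doc(["a", "b", "c", "d", "e"])
        assert len(apply_policy(doc, {1, 3}, "mask")) == 5
        assert len(apply_policy(doc, {1, 3}, "delete")) == 3
        assert apply_policy(doc, {1}, "unk").tokens == ("a", "<UNK>", "c", "d", "e")

    def test_original_document_untouched(self):
        doc = _doc(["a", "b"])
        apply_policy(doc, {0}, "mask")
        assert doc.tokens == ("a", "b")

    def test_out_of_range_position_rejected(self):
        with pytest.raises(IndexError):
            apply_policy(_doc(["a"]), {3}, "mask")

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            apply_policy(_doc(["a"]), {0}, "drop")


class TestDeletionCurve:
    def test_constant_scorer_flat_curve(self, constant_scorer):
        doc = _doc([f"t{i}" for i in range(6)])
        expl = _expl(doc.tokens, [0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        curve = deletion_curve(doc, constant_scorer, expl, 5)
        assert np.allclose(curve.drops, 0.0)
        assert auc_del(curve) == 0.0

    def test_planted_scorer_step_curve(self, planted_scorer_factory, planted_setup):
        lexicon = planted_setup.lexicon
        scorer = planted_scorer_factory(lexicon)
        sig = sorted(lexicon.tokens[0])[0]
        doc = _doc([sig, "n1", "n2", "n3"])
        expl = _expl(doc.tokens, [0.9, 0.01, 0.02, 0.01])
        curve = deletion_curve(doc, scorer, expl, 3, policy="mask")
        # masking the single signal token drops 0.9 -> 0.1 for every k >= 1
        assert np.allclose(curve.drops, 0.8)

    def test_auc_is_hand_mean(self):
        curve = DeletionCurve(0, "probability", "mask", 0.9, np.array([0.1, 0.2, 0.3]))
        assert auc_del(curve) == pytest.approx(0.2, abs=1e-15)

    def test_auc_exact_vs_naive_loop(self):
        rng = np.random.default_rng(0)
        drops = rng.random(10)
        curve = DeletionCurve(0, "probability", "mask", 0.5, drops)
        naive = sum(float(d) for d in drops) / len(drops)
        assert auc_del(curve) == pytest.approx(naive, abs=1e-12)

    def test_prefix_property_on_nondecreasing_curve(self):
        drops = np.array([0.05, 0.1, 0.1, 0.2, 0.2, 0.25, 0.3, 0.3, 0.35, 0.4])
        c10 = DeletionCurve(0, "probability", "mask", 0.9, drops)
        c5 = DeletionCurve(0, "probability", "mask", 0.9, drops[:5])
        assert auc_del(c10) >= auc_del(c5)

    def test_monotone_scorer_gives_nondecreasing_drops(self):
        class CountScorer:
            # score strictly decreases with each signal token removed
            def score(self, token_lists, class_index, basis="probability"):
                return np.array(
                    [0.1 + 0.08 * sum(t.startswith("sig") for t in toks) for toks in token_lists]
                )

        doc = _doc(["siga", "n1", "sigb", "n2", "sigc", "n3", "sigd"])
        expl = _expl(doc.tokens, [0.4, 0.0, 0.3, 0.0, 0.2, 0.0, 0.1])
        curve = deletion_curve(doc, CountScorer(), expl, 7)
        assert np.all(np.diff(curve.drops) >= -1e-12)

    def test_delete_policy_can_empty_document(self, constant_scorer):
        doc = _doc(["a", "b"])
        expl = _expl(doc.tokens, [0.5, 0.4])
        curve = deletion_curve(doc, constant_scorer, expl, 2, policy="delete")
        assert curve.k == 2  # empty doc scored as single [MASK]


class TestSuffComp:
    def test_k_at_least_length_gives_zero_sufficiency(self, constant_scorer):
        doc = _doc(["a", "b", "c"])
        expl = _expl(doc.tokens, [0.3, 0.2, 0.1])
        suff, comp = sufficiency_comprehensiveness(doc, constant_scorer, expl, 5)
        assert suff == pytest.approx(0.0, abs=1e-12)

    def test_single_token_scorer(self):
        class TopOnly:
            def score(self, token_lists, class_index, basis="probability"):
                return np.array([0.9 if "key" in toks else 0.1 for toks in token_lists])

        doc = _doc(["key", "n1", "n2", "n3", "n4"])
        expl = _expl(doc.tokens, [0.8, 0.01, 0.01, 0.01, 0.01])
        suff, comp = sufficiency_comprehensiveness(doc, TopOnly(), expl, 1)
        assert suff == pytest.approx(0.0, abs=1e-12)  # keeping "key" suffices
        assert comp == pytest.approx(0.8, abs=1e-12)  # dropping it removes signal

    def test_comp_equals_mask_curve_at_k(self, planted_setup):
        """Comp(K) is definitionally the mask-policy deletion curve at
        step K: exact equality on the trained scorer."""
        s = planted_setup
        i, c = s.true_positives[1]
        doc = s.corpus[i]
        expl = explain(
            doc, s.scorer, c, ExplainerConfig(n_samples=600, top_k=5, seed=2)
        )
        k = 5
        curve = deletion_curve(doc, s.scorer, expl, k, policy="mask")
        _, comp = sufficiency_comprehensiveness(doc, s.scorer, expl, k)
        assert comp == curve.drops[k - 1]


class TestStability:
    def test_identical_runs_full_overlap_and_tau(self):
        e = _expl(list("abcdef"), [0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        assert overlap_at_k([e, e, e], 3) == 1.0
        assert kendall_stability([e, e], 3) == pytest.approx(1.0)

    def test_disjoint_top_sets_zero_overlap(self):
        a = _expl(list("abcdef"), [0.9, 0.8, 0.7, 0.0, 0.0, 0.0])
        b = _expl(list("abcdef"), [0.0, 0.0, 0.0, 0.9, 0.8, 0.7])
        assert overlap_at_k([a, b], 3) == 0.0

    def test_hand_jaccard_half(self):
        # top-3 sets {0,1,2} vs {0,1,3} -> |A&B|/|A|B| = 2/4
        a = _expl(list("abcde"), [0.9, 0.8, 0.7, 0.1, 0.0])
        b = _expl(list("abcde"), [0.9, 0.8, 0.1, 0.7, 0.0])
        assert overlap_at_k([a, b], 3) == pytest.approx(0.5)

    def test_kendall_reversed_ranking(self):
        a = _expl(list("abc"), [0.1, 0.2, 0.3])
        b = _expl(list("abc"), [0.3, 0.2, 0.1])
        assert kendall_stability([a, b]) == pytest.approx(-1.0)

    def test_kendall_one_third_hand_case(self):
        # scores (1,2,3) vs (1,3,2): one discordant pair of three
        a = _expl(list("abc"), [1.0, 2.0, 3.0])
        b = _expl(list("abc"), [1.0, 3.0, 2.0])
        assert kendall_stability([a, b]) == pytest.approx(1 / 3)

    def test_fewer_than_two_runs_rejected(self):
        e = _expl(list("ab"), [0.5, 0.1])
        with pytest.raises(ValueError):
            overlap_at_k([e], 2)
        with pytest.raises(ValueError):
            kendall_stability([e])


class TestRobustnessSuite:
    def test_identical_seeds_give_perfect_stability(self, planted_setup):
        s = planted_setup
        i, c = s.true_positives[2]
        faith, stab, policies = robustness_suite(
            [s.corpus[i]],
            s.scorer,
            [c],
            ExplainerConfig(n_samples=400, top_k=5, seed=0),
            seeds=[7, 7, 7],
        )
        assert stab.per_instance_overlap[0] == pytest.approx(1.0)
        assert stab.per_instance_tau[0] == pytest.approx(1.0)
        assert stab.per_instance_auc_sd[0] == pytest.approx(0.0, abs=1e-15)

    def test_constant_scorer_zero_auc_all_policies(self, constant_scorer):
        docs = [_doc([f"t{i}" for i in range(8)], did="x")]
        faith, stab, policies = robustness_suite(
            docs,
            constant_scorer,
            [0],
            ExplainerConfig(n_samples=300, top_k=4, seed=0),
            seeds=[1, 2],
        )
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in policies.values())
        assert faith.per_instance_auc[0] == pytest.approx(0.0, abs=1e-12)

    def test_delete_at_least_mask_on_trained_fixture(self, planted_setup):
        """Hard deletion removes the token's evidence entirely (the
        position disappears from pooling), so its mean AUC is at least the
        mask policy's on the planted-lexicon fixture."""
        s = planted_setup
        picks = s.true_positives[:6]
        docs = [s.corpus[i] for i, _ in picks]
        classes = [c for _, c in picks]
        _, _, policies = robustness_suite(
            docs,
            s.scorer,
            classes,
            ExplainerConfig(n_samples=1500, top_k=5, seed=0),
            seeds=[1, 2],
        )
        assert policies["delete"] >= policies["mask"]
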