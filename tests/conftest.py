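"""Shared fixtures: a planted-lexicon corpus with a trained reference
backbone, reused by the explainer, faithfulness and acceptance tests."""

from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from softvote import backbones as bb
from softvote.experiment import ExperimentConfig, prepare_data
from softvote.folds import tri_split
from softvote.fusion import single_backbone_scorer
from softvote.synth import GeneratorConfig, planted_tokens


@pytest.fixture(scope="session")
def planted_setup():
    """N=2000 planted-lexicon corpus, 80-5-15 split, one full-vocabulary
    reference backbone, its text scorer, and the test-partition true
    positives (doc index, label) with at least one planted token."""
    cfg = ExperimentConfig(generator=GeneratorConfig(n_docs=2000, seed=11), seed=11)
    corpus, labels, lexicon, vz = prepare_data(cfg)
    plan = tri_split(labels, seed=11)
    fold = plan.folds[0]
    feats = bb.view_features(corpus, vz, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        weights = bb.compute_class_weights(labels.subset(fold.train))
        model = bb.train_reference_backbone(
            feats[fold.train],
            labels.subset(fold.train),
            weights=weights,
            val_features=feats[fold.val],
            val_labels=labels.subset(fold.val),
        )
    scorer = single_backbone_scorer(vz, model)
    probs = model.predict_proba(feats[fold.test]).values
    onehot = labels.one_hot()
    true_positives = []
    for i_local, i in enumerate(fold.test):
        for c in range(labels.n_labels):
            if (
                onehot[i, c]
                and probs[i_local, c] >= 0.5
                and planted_tokens(corpus[i], c, lexicon)
            ):
                true_positives.append((int(i), c))
                break
    return SimpleNamespace(
        corpus=corpus,
        labels=labels,
        lexicon=lexicon,
        vectorizer=vz,
        model=model,
        scorer=scorer,
        features=feats,
        fold=fold,
        true_positives=true_positives,
    )


class PlantedScorer:
    """Deterministic scorer: 0.9 if any planted token of the class is
    present, else 0.1 (used as a known-ground-truth model)."""

    def __init__(self, lexicon):
        self.lexicon = lexicon

    def score(self, token_lists, class_index, basis="probability"):
        wanted = self.lexicon.tokens[class_index]
        out = np.array(
            [0.9 if any(t in wanted for t in toks) else 0.1 for toks in token_lists]
        )
        if basis == "logit":
            return np.log(out / (1 - out))
        return out


class TokenLinearScorer:
    """Scorer linear in token presence: b0 + sum of per-token weights of
    the tokens present.  Linear in indicator space for documents whose
    tokens are unique."""

    def __init__(self, token_weights: dict, intercept: float = 0.0):
        self.token_weights = token_weights
        self.intercept = intercept

    def score(self, token_lists, class_index, basis="probability"):
        return np.array(
            [
                self.intercept
                + sum(self.token_weights.get(t, 0.0) for t in toks)
                for toks in token_lists
            ]
        )


class ConstantScorer:
    def __init__(self, value: float = 0.5):
        self.value = value

    def score(self, token_lists, class_index, basis="probability"):
        return np.full(len(token_lists), self.value)


@pytest.fixture
def planted_scorer_factory():
    return PlantedScorer


@pytest.fixture
def token_linear_scorer_factory():
    return TokenLinearScorer


@pytest.fixture
def constant_scorer():
    return ConstantScorer()
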