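"""Synthetic corpora with planted token-label associations.

Every downstream stage of the package (training, fusion, threshold
calibration, explanation, faithfulness validation) needs a corpus whose
ground truth is fully known.  This module generates one: each label owns a
small disjoint lexicon of signal tokens; a document positive for a label
emits each of that label's tokens independently with probability
``signal_prob``; remaining positions are filled from a Zipf-distributed
noise vocabulary and the token order is shuffled.

Label structure emulates the two corpus shapes the package targets:

* multi-label with skewed per-label positive rates and controllable
  pairwise co-occurrence (emotion-style, C=8 by default);
* multi-class with a strongly imbalanced class mixture (severity-style,
  C=4 by default, mixture ~(0.44, 0.02, 0.45, 0.09)).

Co-occurrence is induced by a Gaussian-copula draw: latent label scores are
sampled from N(0, R) where R has unit diagonal and off-diagonal entries
equal to the configured association strengths, and label ``c`` is positive
iff its latent score falls below the ``base_rate_c`` quantile.  Marginal
positive rates are therefore exact while pairwise association is controlled
continuously.

Tokens are opaque symbols; no attempt is made to imitate natural-language
syntax or register.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .corpus import MULTI_CLASS, MULTI_LABEL, TASK_MODES, Corpus, Document, LabelMatrix

#: Default per-label positive rates (multi-label): skewed from a frequent
#: majority label down to a 5% minority label.
DEFAULT_MULTILABEL_RATES = (0.45, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10, 0.05)

#: Default class mixture (multi-class): strong imbalance with one class
#: near 2%, mirroring a severity-style distribution.
DEFAULT_MULTICLASS_MIXTURE = (0.44, 0.02, 0.45, 0.09)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic corpus generator.

    ``label_base_rates`` are per-label positive probabilities in
    multi-label mode and a class mixture (summing to 1) in multi-class
    mode.  ``cooccurrence`` is a C x C symmetric matrix of association
    strengths in [-1, 1] (multi-label only; the diagonal is ignored).
    """

    n_docs: int = 1000
    n_labels: int = 8
    task_mode: str = MULTI_LABEL
    label_base_rates: tuple[float, ...] | None = None
    cooccurrence: np.ndarray | None = None
    lexicon_size_per_label: int = 6
    signal_prob: float = 0.5
    noise_vocab_size: int = 300
    doc_length_range: tuple[int, int] = (15, 50)
    zipf_exponent: float = 1.1
    seed: int = 0
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.task_mode not in TASK_MODES:
            raise ValueError(f"task_mode must be one of {TASK_MODES}")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if self.n_labels < 1:
            raise ValueError("n_labels must be >= 1")
        if self.label_base_rates is None:
            default = (
                DEFAULT_MULTILABEL_RATES
                if self.task_mode == MULTI_LABEL
                else DEFAULT_MULTICLASS_MIXTURE
            )
            if self.n_labels == len(default):
                self.label_base_rates = default
            elif self.task_mode == MULTI_LABEL:
                self.label_base_rates = tuple(
                    float(r) for r in np.linspace(0.45, 0.05, self.n_labels)
                )
            else:
                self.label_base_rates = tuple([1.0 / self.n_labels] * self.n_labels)
        self.label_base_rates = tuple(float(r) for r in self.label_base_rates)
        if len(self.label_base_rates) != self.n_labels:
            raise ValueError("label_base_rates must have length n_labels")
        if any(not 0.0 <= r <= 1.0 for r in self.label_base_rates):
            raise ValueError("label_base_rates entries must lie in [0, 1]")
        if self.task_mode == MULTI_CLASS:
            if abs(sum(self.label_base_rates) - 1.0) > 1e-9:
                raise ValueError("label_base_rates must sum to 1 in multi-class mode")
        if self.cooccurrence is not None:
            self.cooccurrence = np.asarray(self.cooccurrence, dtype=float)
            if self.cooccurrence.shape != (self.n_labels, self.n_labels):
                raise ValueError("cooccurrence must be C x C")
            if not np.allclose(self.cooccurrence, self.cooccurrence.T):
                raise ValueError("cooccurrence must be symmetric")
            if np.abs(self.cooccurrence).max() > 1.0:
                raise ValueError("cooccurrence entries must lie in [-1, 1]")
        if not 0.0 <= self.signal_prob <= 1.0:
            raise ValueError("signal_prob must lie in [0, 1]")
        if self.lexicon_size_per_label < 1:
            raise ValueError("lexicon_size_per_label must be >= 1")
        if self.noise_vocab_size < 1:
            raise ValueError("noise_vocab_size must be >= 1")
        lo, hi = self.doc_length_range
        if lo < 3:
            raise ValueError("doc_length_range minimum must be >= 3")
        if hi < lo:
            raise ValueError("doc_length_range must be (min, max) with max >= min")
        if not self.label_names:
            self.label_names = [f"label{c}" for c in range(self.n_labels)]
        if len(self.label_names) != self.n_labels:
            raise ValueError("label_names must have length n_labels")


@dataclass
class Lexicon:
    """Ground-truth planted lexicons: label index -> set of signal tokens."""

    tokens: dict[int, frozenset[str]]
    signal_prob: float

    def __post_init__(self) -> None:
        all_tokens: set[str] = set()
        for toks in self.tokens.values():
            if all_tokens & set(toks):
                raise ValueError("planted lexicons must be pairwise disjoint")
            all_tokens |= set(toks)

    def label_of(self, token: str) -> int | None:
        for c, toks in self.tokens.items():
            if token in toks:
                return c
        return None


def _correlation_matrix(config: GeneratorConfig) -> np.ndarray:
    c = config.n_labels
    if config.cooccurrence is None:
        return np.eye(c)
    corr = np.array(config.cooccurrence, dtype=float)
    np.fill_diagonal(corr, 1.0)
    # Nudge to the nearest PSD matrix if the requested associations are
    # jointly infeasible.
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < 1e-10:
        vals = np.clip(vals, 1e-10, None)
        corr = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def _draw_labels(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n, c = config.n_docs, config.n_labels
    rates = np.asarray(config.label_base_rates)
    if config.task_mode == MULTI_CLASS:
        return rng.choice(c, size=n, p=rates)
    corr = _correlation_matrix(config)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(c))
    z = rng.standard_normal((n, c)) @ chol.T
    thresholds = stats.norm.ppf(np.clip(rates, 1e-12, 1 - 1e-12))
    return (z < thresholds).astype(np.int8)


def build_lexicon(config: GeneratorConfig) -> Lexicon:
    """Deterministic disjoint lexicons: label c owns tokens ``sig{c}tok{j}``."""
    tokens = {
        c: frozenset(
            f"sig{c}tok{j}" for j in range(config.lexicon_size_per_label)
        )
        for c in range(config.n_labels)
    }
    return Lexicon(tokens=tokens, signal_prob=config.signal_prob)


def noise_vocabulary(config: GeneratorConfig) -> list[str]:
    return [f"word{j:05d}" for j in range(config.noise_vocab_size)]


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[Corpus, LabelMatrix, Lexicon]:
    """Generate a corpus with planted token-label associations.

    Deterministic given ``config.seed``.  Returns the corpus, its label
    matrix, and the ground-truth lexicon used to plant signal tokens.
    """
    rng = np.random.default_rng(config.seed)
    lexicon = build_lexicon(config)
    noise_vocab = np.array(noise_vocabulary(config))
    ranks = np.arange(1, config.noise_vocab_size + 1, dtype=float)
    zipf_p = ranks ** (-config.zipf_exponent)
    zipf_p /= zipf_p.sum()

    raw = _draw_labels(config, rng)
    if config.task_mode == MULTI_CLASS:
        labels = LabelMatrix(MULTI_CLASS, list(config.label_names), raw)
        positives_per_doc = [[int(k)] for k in raw]
    else:
        labels = LabelMatrix(MULTI_LABEL, list(config.label_names), raw)
        positives_per_doc = [list(np.flatnonzero(row)) for row in raw]

    lo, hi = config.doc_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_docs)
    docs: list[Document] = []
    width = len(str(config.n_docs - 1))
    for i in range(config.n_docs):
        toks: list[str] = []
        for c in positives_per_doc[i]:
            for tok in sorted(lexicon.tokens[c]):
                if rng.random() < config.signal_prob:
                    toks.append(tok)
        n_fill = max(int(lengths[i]) - len(toks), 0)
        if n_fill:
            picks = rng.choice(config.noise_vocab_size, size=n_fill, p=zipf_p)
            toks.extend(str(noise_vocab[j]) for j in picks)
        rng.shuffle(toks)
        docs.append(
            Document(
                id=f"doc{i:0{width}d}",
                raw_text=" ".join(toks),
                tokens=tuple(toks),
            )
        )
    return Corpus(docs), labels, lexicon


def planted_tokens(doc: Document, label: int, lexicon: Lexicon) -> set[int]:
    """Positions in ``doc.tokens`` holding planted tokens of ``label``.

    Duplicated planted tokens contribute every occurrence position.  The
    empty set is a valid result (a positive document need not have emitted
    any of its label's tokens).
    """
    if label not in lexicon.tokens:
        raise KeyError(f"unknown label index {label}")
    wanted = lexicon.tokens[label]
    return {i for i, tok in enumerate(doc.tokens) if tok in wanted}
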