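"""From-scratch local-surrogate (LIME-style) token attribution.

To explain one prediction, the model is queried on S perturbed copies of
the document in which random token subsets are replaced by a mask token.
Each perturbation is encoded as a binary indicator vector over positions
(1 = token kept) and weighted by an exponential similarity kernel

    K(x, x') = exp(-d^2 / kappa^2),    d = number of masked positions,

so perturbations close to the original dominate the fit.  A weighted
ridge regression from indicators to the model's class score (probability
or logit basis) yields per-position coefficients — the token importances —
and the top-K positions by absolute coefficient form the explanation.

Perturbation sampling masks a uniformly drawn count m in {1..max(1, L-1)}
of uniformly chosen distinct positions; row 0 is always the unperturbed
document.  Attribution is per position, not per token type: duplicated
tokens receive separate scores, which is what deletion-curve validation
operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Document

MASK_TOKEN = "[MASK]"


@dataclass
class ExplainerConfig:
    """Configuration of the surrogate explainer.

    ``kappa=None`` selects the length-proportional default
    ``max(1, 0.25 * L)``, keeping kernel mass on near neighbors across
    document lengths.
    """

    n_samples: int = 5000
    kappa: float | None = None
    top_k: int = 10
    basis: str = "probability"
    ridge_lambda: float = 1e-6
    mask_token: str = MASK_TOKEN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValueError("n_samples must be >= 100")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.basis not in ("probability", "logit"):
            raise ValueError("basis must be 'probability' or 'logit'")

    def kappa_for(self, length: int) -> float:
        return self.kappa if self.kappa is not None else max(1.0, 0.25 * length)


@dataclass
class Explanation:
    """Signed per-position token attributions for one document/class."""

    doc_id: str
    class_index: int
    tokens: tuple[str, ...]
    scores: np.ndarray
    intercept: float
    top_positions: list[int]
    config: ExplainerConfig = field(repr=False, default=None)

    def ranked_positions(self) -> list[int]:
        """All positions by |score| descending, ties by earlier position."""
        return sorted(
            range(len(self.scores)), key=lambda i: (-abs(self.scores[i]), i)
        )

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "class_index": self.class_index,
            "tokens": list(self.tokens),
            "scores": list(map(float, self.scores)),
            "intercept": self.intercept,
            "top_positions": self.top_positions,
        }


def sample_perturbations(
    doc: Document,
    n_samples: int,
    seed: int,
    mask_token: str = MASK_TOKEN,
) -> tuple[np.ndarray, list[tuple[str, ...]]]:
    """Indicator matrix (S x L) and the corresponding perturbed token lists.

    Row 0 is the unperturbed document.  Every other row masks m positions,
    with m uniform on {1..max(1, L-1)} and the positions uniform without
    replacement.  Deterministic given the seed.
    """
    L = len(doc.tokens)
    if L < 1:
        raise ValueError("document must have at least one token")
    rng = np.random.default_rng(seed)
    Z = np.ones((n_samples, L), dtype=np.int8)
    max_masked = max(1, L - 1)
    for s in range(1, n_samples):
        m = int(rng.integers(1, max_masked + 1))
        pos = rng.choice(L, size=m, replace=False)
        Z[s, pos] = 0
    perturbed = [
        tuple(
            tok if Z[s, j] else mask_token for j, tok in enumerate(doc.tokens)
        )
        for s in range(n_samples)
    ]
    return Z, perturbed


def kernel_weight(indicator_row: np.ndarray, kappa: float) -> float:
    """Similarity kernel exp(-d^2/kappa^2), d = number of masked positions."""
    d = float(len(indicator_row) - np.asarray(indicator_row).sum())
    return float(np.exp(-(d**2) / kappa**2))


def kernel_weights(indicators: np.ndarray, kappa: float) -> np.ndarray:
    Z = np.asarray(indicators, dtype=float)
    d = Z.shape[1] - Z.sum(axis=1)
    return np.exp(-(d**2) / kappa**2)


def fit_surrogate(
    indicators: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    ridge_lambda: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Weighted ridge fit of targets on indicators.

    Minimizes ``sum_s w_s (b0 + z_s . beta - t_s)^2 + lambda ||beta||^2``
    (intercept unpenalized).  Invariant to rescaling all sample weights.
    Deterministic; degenerate designs (all rows identical) are rejected.
    """
    Z = np.asarray(indicators, dtype=float)
    t = np.asarray(targets, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("targets must be finite")
    if (Z == Z[0]).all():
        raise ValueError("degenerate design: all perturbation rows identical")
    w = w / w.sum()  # scale invariance
    S, L = Z.shape
    X = np.hstack([np.ones((S, 1)), Z])
    XtW = X.T * w
    A = XtW @ X
    reg = np.eye(L + 1) * ridge_lambda
    reg[0, 0] = 0.0
    coef = np.linalg.solve(A + reg, XtW @ t)
    return coef[1:], float(coef[0])


def explain(
    doc: Document,
    scorer,
    class_index: int,
    config: ExplainerConfig | None = None,
) -> Explanation:
    """Full surrogate pipeline: sample, weight, fit, rank.

    ``scorer`` must expose ``score(token_lists, class_index, basis)``; the
    fast path ``score_indicator(doc, Z, class_index, basis)`` is used when
    available.  Top-K positions are chosen by absolute coefficient, ties
    broken by earlier position.  Same seed, same explanation.
    """
    config = config or ExplainerConfig()
    Z, perturbed = sample_perturbations(
        doc, config.n_samples, config.seed, config.mask_token
    )
    if hasattr(scorer, "score_indicator"):
        targets = scorer.score_indicator(doc, Z, class_index, config.basis)
    else:
        targets = scorer.score(perturbed, class_index, config.basis)
    kappa = config.kappa_for(len(doc.tokens))
    w = kernel_weights(Z, kappa)
    coefs, intercept = fit_surrogate(Z, targets, w, config.ridge_lambda)
    ranked = sorted(
        range(len(coefs)), key=lambda i: (-abs(coefs[i]), i)
    )
    k = min(config.top_k, len(coefs))
    return Explanation(
        doc_id=doc.id,
        class_index=class_index,
        tokens=doc.tokens,
        scores=coefs,
        intercept=intercept,
        top_positions=ranked[:k],
        config=config,
    )


def tune_kappa(
    docs,
    scorer,
    class_indices,
    config: ExplainerConfig,
    multipliers=(0.1, 0.25, 0.5, 1.0),
    top_k: int = 5,
) -> float:
    """Kernel-width tuning hook: pick the length multiplier maximizing mean
    deletion-curve faithfulness (AUC_del) on a small validation subset."""
    from .faithfulness import auc_del, deletion_curve

    best_mult, best_score = multipliers[0], -np.inf
    for mult in multipliers:
        total = 0.0
        for doc, c in zip(docs, class_indices):
            cfg = ExplainerConfig(
                n_samples=config.n_samples,
                kappa=max(1.0, mult * len(doc.tokens)),
                top_k=top_k,
                basis=config.basis,
                ridge_lambda=config.ridge_lambda,
                mask_token=config.mask_token,
                seed=config.seed,
            )
            expl = explain(doc, scorer, c, cfg)
            curve = deletion_curve(doc, scorer, expl, top_k, "mask", config.basis)
            total += auc_del(curve)
        if total > best_score:
            best_score, best_mult = total, mult
    return best_mult
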