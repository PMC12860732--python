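"""Validation-weighted soft-voting fusion and per-class threshold calibration.

Each ensemble member i contributes its class probabilities p_ij(x) with a
static weight W_i proportional to its validation macro-F1 score s_i:

    W_i = s_i / sum_k s_k,        P_j(x) = sum_i W_i p_ij(x).

Weights are computed once per fold on validation data and frozen for that
fold's test partition.  Multi-class decisions are the fused argmax;
multi-label decisions threshold each class at a calibrated tau_c chosen on
validation data by maximizing that class's F1 over a fixed grid (default
0.30 to 0.70 in steps of 0.05, ties resolved toward the smallest tau,
which favors recall).

The ensemble-variance identity

    Var[sum_m a_m p_m] = sum_m a_m^2 Var[p_m]
                         + 2 sum_{i<j} a_i a_j Cov(p_i, p_j)

is exposed as a diagnostic: heterogeneous members lower the covariance
term, which is the mechanism by which probability averaging helps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .backbones import LinearBackbone, ProbMatrix, VocabularyView
from .corpus import MULTI_CLASS, MULTI_LABEL, Document
from .embeddings import HybridVectorizer, hybrid_vector
from .metrics import DEFAULT_EPS

#: default per-class threshold calibration grid: [0.3, 0.7] step 0.05
DEFAULT_GRID: tuple[float, ...] = tuple(
    round(0.30 + 0.05 * i, 2) for i in range(9)
)


def compute_fusion_weights(val_scores) -> np.ndarray:
    """Normalized soft-voting weights W_i = s_i / sum_k s_k.

    Falls back to uniform weights (with a warning) when every validation
    score is zero.
    """
    s = np.asarray(val_scores, dtype=float)
    if s.ndim != 1 or len(s) < 1:
        raise ValueError("val_scores must be a non-empty 1-D array")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("validation scores must lie in [0, 1]")
    total = s.sum()
    if total == 0.0:
        warnings.warn(
            "all validation scores are zero; falling back to uniform weights",
            stacklevel=2,
        )
        return np.full(len(s), 1.0 / len(s))
    return s / total


def fuse_probabilities(members: list[ProbMatrix], weights) -> ProbMatrix:
    """Weighted mean of member probabilities, elementwise."""
    if not members:
        raise ValueError("at least one member required")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(members):
        raise ValueError("one weight per member required")
    shape = members[0].shape
    mode = members[0].task_mode
    for i, m in enumerate(members):
        if m.shape != shape or m.task_mode != mode:
            raise ValueError(f"member {i} has mismatched shape or task mode")
    fused = np.zeros(shape)
    for wi, m in zip(w, members):
        fused += wi * m.values
    return ProbMatrix(np.clip(fused, 0.0, 1.0), mode)


def calibrate_thresholds(
    fused_val: ProbMatrix,
    val_labels,
    grid=DEFAULT_GRID,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Per-class decision thresholds maximizing class-wise F1 on validation.

    For each class the whole grid is scored exhaustively; ties go to the
    smallest threshold.  A class with zero validation positives gets the
    grid midpoint (with a warning).
    """
    if fused_val.task_mode != MULTI_LABEL:
        raise ValueError("threshold calibration applies to multi-label mode only")
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    y = np.asarray(
        val_labels.one_hot() if hasattr(val_labels, "one_hot") else val_labels
    )
    probs = fused_val.values
    n, c = probs.shape
    taus = np.empty(c)
    midpoint = grid[len(grid) // 2]
    for j in range(c):
        pos = y[:, j].astype(bool)
        if not pos.any():
            warnings.warn(
                f"class {j} has no validation positives; using grid midpoint",
                stacklevel=2,
            )
            taus[j] = midpoint
            continue
        best_f1, best_tau = -1.0, grid[0]
        for tau in grid:
            pred = probs[:, j] >= tau
            tp = float((pred & pos).sum())
            fp = float((pred & ~pos).sum())
            fn = float((~pred & pos).sum())
            p = tp / (tp + fp + eps)
            r = tp / (tp + fn + eps)
            f1 = 2 * p * r / (p + r + eps)
            if f1 > best_f1 + 1e-15:
                best_f1, best_tau = f1, tau
        taus[j] = best_tau
    return taus


def decide_multilabel(fused: ProbMatrix, taus) -> np.ndarray:
    """Binary decisions: label c is predicted iff P_c >= tau_c (inclusive)."""
    if fused.task_mode != MULTI_LABEL:
        raise ValueError("decide_multilabel requires multi-label probabilities")
    taus = np.asarray(taus, dtype=float)
    return (fused.values >= taus[None, :]).astype(np.int8)


def decide_multiclass(fused: ProbMatrix) -> np.ndarray:
    """Class decisions: per-row argmax, ties to the lowest class index."""
    if fused.task_mode != MULTI_CLASS:
        raise ValueError("decide_multiclass requires multi-class probabilities")
    return fused.values.argmax(axis=1)


def variance_decomposition(
    members: list[ProbMatrix], weights, class_index: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Empirical ensemble-variance identity for one class column.

    Returns ``(lhs, member_variances, covariance_matrix)`` where ``lhs``
    is the empirical variance of the fused class probability over
    documents and the decomposition
    ``sum a_m^2 Var[p_m] + 2 sum_{i<j} a_i a_j Cov(p_i, p_j)`` (computable
    from the returned pieces) agrees with it to numerical precision.
    """
    if members[0].shape[0] < 2:
        raise ValueError("variance decomposition needs >= 2 documents")
    w = np.asarray(weights, dtype=float)
    cols = np.stack([m.values[:, class_index] for m in members])  # m x n
    fused = w @ cols
    lhs = float(fused.var(ddof=0))
    cov = np.cov(cols, ddof=0).reshape(len(members), len(members))
    return lhs, np.diag(cov).copy(), cov


def decomposition_rhs(weights, cov: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w @ cov @ w)


@dataclass
class FusionModel:
    """A frozen per-fold fusion: member names, weights, thresholds."""

    member_names: list[str]
    weights: np.ndarray
    task_mode: str
    thresholds: np.ndarray | None = None
    grid: tuple[float, ...] = DEFAULT_GRID
    weight_metric: str = "val-macro-F1"
    fold_id: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("fusion weights must sum to 1 (1e-12)")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            lo, hi = min(self.grid), max(self.grid)
            if (self.thresholds < lo - 1e-12).any() or (
                self.thresholds > hi + 1e-12
            ).any():
                raise ValueError("thresholds must lie within the grid range")

    def fuse(self, members: list[ProbMatrix]) -> ProbMatrix:
        return fuse_probabilities(members, self.weights)

    def decide(self, members: list[ProbMatrix]) -> np.ndarray:
        fused = self.fuse(members)
        if self.task_mode == MULTI_CLASS:
            return decide_multiclass(fused)
        if self.thresholds is None:
            raise RuntimeError("multi-label fusion model has no thresholds")
        return decide_multilabel(fused, self.thresholds)

    def to_json(self, path) -> None:
        obj = {
            "member_names": self.member_names,
            "weights": self.weights.tolist(),
            "task_mode": self.task_mode,
            "thresholds": None
            if self.thresholds is None
            else self.thresholds.tolist(),
            "grid": list(self.grid),
            "weight_metric": self.weight_metric,
            "fold_id": self.fold_id,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "FusionModel":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            member_names=obj["member_names"],
            weights=np.array(obj["weights"]),
            task_mode=obj["task_mode"],
            thresholds=None
            if obj["thresholds"] is None
            else np.array(obj["thresholds"]),
            grid=tuple(obj["grid"]),
            weight_metric=obj["weight_metric"],
            fold_id=obj["fold_id"],
        )


# -- token-level scoring (used by the explainer and faithfulness checks) ---


def _to_logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(p / (1.0 - p))


class EnsembleTextScorer:
    """Scores raw token sequences with the fused ensemble.

    Members are ``(view, backbone)`` pairs sharing one hybrid vectorizer;
    a member's features are the mean of the (view-filtered) token hybrid
    vectors.  Exposes a batch scorer over token lists and a fast path over
    mask-indicator matrices for one document, where pooled features for
    all perturbations reduce to a single matrix product.
    """

    def __init__(
        self,
        vectorizer: HybridVectorizer,
        members: list[tuple[VocabularyView | None, LinearBackbone]],
        weights,
        mask_token: str = "[MASK]",
    ):
        if not members:
            raise ValueError("at least one member required")
        self.vectorizer = vectorizer
        self.members = members
        self.weights = np.asarray(weights, dtype=float)
        self.task_mode = members[0][1].task_mode
        self.mask_token = mask_token
        self._cache: dict[str, np.ndarray] = {}

    def _vec(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            vec = hybrid_vector(token, self.vectorizer)
            self._cache[token] = vec
        return vec

    def _pool(self, tokens, view: VocabularyView | None) -> np.ndarray:
        toks = tuple(tokens) if view is None else view.filter(tuple(tokens))
        if not toks:
            toks = (self.mask_token,)
        acc = np.zeros(self.vectorizer.output_dim)
        for t in toks:
            acc += self._vec(t)
        return acc / len(toks)

    def predict_proba_tokens(self, token_lists) -> ProbMatrix:
        """Fused probabilities for a batch of token sequences."""
        fused = None
        for w, (view, backbone) in zip(self.weights, self.members):
            feats = np.stack([self._pool(toks, view) for toks in token_lists])
            p = backbone.predict_proba(feats).values
            fused = w * p if fused is None else fused + w * p
        return ProbMatrix(np.clip(fused, 0.0, 1.0), self.task_mode)

    def score(self, token_lists, class_index: int, basis: str = "probability") -> np.ndarray:
        """Fused score of one class for each token sequence."""
        p = self.predict_proba_tokens(token_lists).values[:, class_index]
        return _to_logit(p) if basis == "logit" else p

    def score_indicator(
        self,
        doc: Document,
        indicators: np.ndarray,
        class_index: int,
        basis: str = "probability",
    ) -> np.ndarray:
        """Fast scoring of mask-perturbations of one document.

        ``indicators`` is an S x L 0/1 matrix; position j of row s keeps
        token j when 1 and replaces it with the mask token when 0.  The
        pooled features of all S perturbations are computed in one matrix
        product per member.
        """
        Z = np.asarray(indicators, dtype=float)
        L = len(doc.tokens)
        if Z.shape[1] != L:
            raise ValueError("indicator width must equal document length")
        fused = None
        for w, (view, backbone) in zip(self.weights, self.members):
            toks = (
                doc.tokens if view is None else view.filter(doc.tokens)
            )
            V = np.stack([self._vec(t) for t in toks])  # L x D
            mask_tok = (
                self.mask_token
                if view is None
                else view.filter((self.mask_token,))[0]
            )
            u = self._vec(mask_tok)
            pooled = (Z @ (V - u[None, :]) + L * u[None, :]) / L
            p = backbone.predict_proba(pooled).values
            fused = w * p if fused is None else fused + w * p
        col = np.clip(fused, 0.0, 1.0)[:, class_index]
        return _to_logit(col) if basis == "logit" else col


def single_backbone_scorer(
    vectorizer: HybridVectorizer,
    backbone: LinearBackbone,
    view: VocabularyView | None = None,
    mask_token: str = "[MASK]",
) -> EnsembleTextScorer:
    """A one-member ensemble scorer (weights = [1.0])."""
    return EnsembleTextScorer(vectorizer, [(view, backbone)], [1.0], mask_token)
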