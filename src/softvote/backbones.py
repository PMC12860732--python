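"""Probabilistic-classifier contract and lightweight reference backbones.

Every ensemble member satisfies a small contract: it is fitted once,
exposes deterministic ``predict_proba`` returning a :class:`ProbMatrix`
(rows on the simplex in multi-class mode), and carries a validation
macro-F1 ``val_score`` used later as its fusion weight.

The bundled reference backbone is a linear model (independent per-label
logistic units in multi-label mode, multinomial logistic in multi-class
mode) over pooled hybrid embeddings, trained by mini-batch Adam on the
imbalance-sensitive losses:

* multi-label — class-weighted binary cross-entropy
  ``-(1/C) sum_c w_c [y_c log s(z_c) + (1-y_c) log(1-s(z_c))]``;
* multi-class — class-weighted cross-entropy ``-w_y log softmax(z)_y``;

with L2 penalty, gradient clipping and early stopping on validation
macro-F1.  Class weights are inverse class frequency normalized to mean 1.
Minority classes can additionally be oversampled on the training fold with
a cap ratio ``r`` (upsampled to at most ``r`` times the majority count).

Heterogeneous ensemble members are created through *feature views*: either
a seeded vocabulary-hash filter (each member sees a different random
subset of the vocabulary, the rest mapping to UNK) or a seeded Gaussian
random projection of the pooled features.  Members trained on different
views make decorrelated errors, which is what probability averaging
exploits.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import MULTI_CLASS, MULTI_LABEL, TASK_MODES, Corpus, LabelMatrix
from .embeddings import HybridVectorizer, hybrid_vector
from .metrics import macro_f1

CLAMP = 1e-12
#: token a vocabulary view substitutes for dropped tokens; absent from all
#: embedding tables, so it resolves to the UNK vector
VIEW_UNK = "[VIEWUNK]"


@dataclass
class ProbMatrix:
    """N x C matrix of class probabilities."""

    values: np.ndarray
    task_mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.task_mode not in TASK_MODES:
            raise ValueError(f"unknown task_mode {self.task_mode!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.task_mode == MULTI_CLASS:
            sums = self.values.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("multi-class rows must sum to 1 (1e-9)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClassWeights:
    """Per-class loss multipliers, inverse class frequency, mean 1."""

    w: np.ndarray
    convention: str = "inverse-frequency, normalized to mean 1"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if (self.w < 0).any():
            raise ValueError("class weights must be nonnegative")

    @classmethod
    def unit(cls, n_classes: int) -> "ClassWeights":
        return cls(np.ones(n_classes), convention="unit")


def compute_class_weights(labels: LabelMatrix) -> ClassWeights:
    """Inverse-frequency class weights, normalized to mean 1.

    Frequency is the class share of documents (multi-class) or the label's
    positive rate (multi-label).  A class with zero positives in the
    training fold is an error: repair the fold (stratification should
    prevent this) rather than training with an infinite weight.
    """
    counts = labels.positive_counts().astype(float)
    if (counts == 0).any():
        missing = [labels.label_names[c] for c in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"classes with zero training positives: {missing}; "
            "repair the fold (stratified splitting should prevent this)"
        )
    freq = counts / len(labels)
    raw = 1.0 / freq
    w = labels.n_labels * raw / raw.sum()
    return ClassWeights(w)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def weighted_bce_loss(
    logits: np.ndarray, y: np.ndarray, weights: ClassWeights
) -> float:
    """Class-weighted binary cross-entropy of one example.

    ``-(1/C) sum_c w_c [y_c log s(z_c) + (1-y_c) log(1-s(z_c))]`` with
    probabilities clamped to [1e-12, 1-1e-12].
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.clip(_sigmoid(z), CLAMP, 1.0 - CLAMP)
    per_class = weights.w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(-per_class.mean())


def weighted_ce_loss(logits: np.ndarray, y: int, weights: ClassWeights) -> float:
    """Class-weighted cross-entropy of one example: ``-w_y log softmax(z)_y``."""
    z = np.asarray(logits, dtype=float)
    p = np.clip(_softmax(z), CLAMP, 1.0 - CLAMP)
    return float(-weights.w[y] * math.log(p[y]))


def oversample_training_fold(
    train_indices: np.ndarray,
    labels: LabelMatrix,
    r: float,
    seed: int,
) -> np.ndarray:
    """Random minority oversampling on a training fold with cap ratio ``r``.

    Multi-class: every class with count below ``r`` times the majority
    count is upsampled with replacement to ``ceil(r * majority)``.
    Multi-label: labels are processed rarest-first; documents positive for
    a deficient label are duplicated until that label's positive count
    reaches ``ceil(r * max positives)`` or the duplication budget (2x the
    original fold size) is exhausted.  Validation/test folds are never
    passed through this function.

    The sampling stream is seeded per class, so for ``r1 < r2`` on the same
    fold and seed the smaller multiset is a sub-multiset of the larger one.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("oversampling cap r must lie in (0, 1]")
    train_indices = np.asarray(train_indices, dtype=np.int64)
    sub = labels.subset(train_indices)
    out = list(train_indices)
    if sub.task_mode == MULTI_CLASS:
        counts = sub.positive_counts()
        majority = int(counts.max())
        target = math.ceil(r * majority)
        for c in range(sub.n_labels):
            members = train_indices[np.asarray(sub.values) == c]
            needed = target - int(counts[c])
            if needed <= 0 or len(members) == 0:
                continue
            rng = np.random.default_rng([seed, c])
            picks = rng.integers(0, len(members), size=needed)
            out.extend(members[picks])
        return np.array(out, dtype=np.int64)

    onehot = sub.one_hot().astype(np.int64)
    counts = onehot.sum(axis=0)
    budget = 2 * len(train_indices)
    target = math.ceil(r * int(counts.max()))
    order = sorted(range(sub.n_labels), key=lambda c: (counts[c], c))
    current = counts.copy()
    for c in order:
        members_pos = np.flatnonzero(onehot[:, c])
        if len(members_pos) == 0:
            continue
        rng = np.random.default_rng([seed, sub.n_labels + c])
        while current[c] < target and len(out) < budget:
            pick = int(rng.integers(0, len(members_pos)))
            row = members_pos[pick]
            out.append(int(train_indices[row]))
            current += onehot[row]
    return np.array(out, dtype=np.int64)


@dataclass
class TrainConfig:
    learning_rate: float = 0.05
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 5
    l2: float = 1e-3
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < self.patience:
            raise ValueError("max_epochs must be >= patience")


class LinearBackbone:
    """Linear probabilistic classifier over pooled features.

    Multi-label: independent logistic units per label; multi-class:
    multinomial logistic regression.  Satisfies the backbone contract:
    ``fit`` then deterministic ``predict_proba``, with ``val_score``
    holding the validation macro-F1 of the best early-stopping epoch.
    """

    def __init__(self, name: str, task_mode: str):
        if task_mode not in TASK_MODES:
            raise ValueError(f"unknown task_mode {task_mode!r}")
        self.name = name
        self.task_mode = task_mode
        self.W: np.ndarray | None = None
        self.b: np.ndarray | None = None
        # per-dimension z-normalization of input features, fitted on the
        # training fold (pooled embedding coordinates are tiny and
        # unevenly scaled otherwise)
        self.feat_mean: np.ndarray | None = None
        self.feat_scale: np.ndarray | None = None
        self.val_score: float = float("nan")
        self.best_epoch: int = -1
        self.n_epochs_run: int = 0

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return X
        return (X - self.feat_mean) / self.feat_scale

    # -- training ---------------------------------------------------------

    def _grad(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        weights: ClassWeights,
    ) -> tuple[np.ndarray, np.ndarray, float]:
        Z = X @ self.W + self.b
        n, c = Z.shape
        if self.task_mode == MULTI_LABEL:
            P = np.clip(_sigmoid(Z), CLAMP, 1.0 - CLAMP)
            loss = float(
                -(weights.w * (Y * np.log(P) + (1 - Y) * np.log(1 - P))).sum()
                / (n * c)
            )
            dZ = weights.w * (P - Y) / (n * c)
        else:
            P = np.clip(_softmax(Z), CLAMP, 1.0 - CLAMP)
            y_idx = Y.astype(int)
            wy = weights.w[y_idx]
            loss = float(-(wy * np.log(P[np.arange(n), y_idx])).mean())
            onehot = np.zeros_like(P)
            onehot[np.arange(n), y_idx] = 1.0
            dZ = (wy[:, None] * (P - onehot)) / n
        gW = X.T @ dZ + self.l2 * self.W
        gb = dZ.sum(axis=0)
        loss += 0.5 * self.l2 * float((self.W**2).sum())
        return gW, gb, loss

    def fit(
        self,
        features: np.ndarray,
        labels: LabelMatrix,
        weights: ClassWeights | None = None,
        config: TrainConfig | None = None,
        val_features: np.ndarray | None = None,
        val_labels: LabelMatrix | None = None,
    ) -> "LinearBackbone":
        config = config or TrainConfig()
        X = np.asarray(features, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        X_raw = X
        self.feat_mean = X.mean(axis=0)
        self.feat_scale = np.maximum(X.std(axis=0), 1e-8)
        X = self._standardize(X)
        c = labels.n_labels
        weights = weights or ClassWeights.unit(c)
        Y = (
            np.asarray(labels.values, dtype=float)
            if labels.task_mode == MULTI_LABEL
            else np.asarray(labels.values)
        )
        rng = np.random.default_rng(config.seed)
        d = X.shape[1]
        self.l2 = config.l2
        self.W = np.zeros((d, c))
        self.b = np.zeros(c)
        # Adam state
        mW = np.zeros_like(self.W)
        vW = np.zeros_like(self.W)
        mb = np.zeros_like(self.b)
        vb = np.zeros_like(self.b)
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        step = 0
        best = -np.inf
        best_params = (self.W.copy(), self.b.copy())
        since_best = 0
        has_val = val_features is not None and val_labels is not None
        for epoch in range(config.max_epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X), config.batch_size):
                idx = order[start : start + config.batch_size]
                gW, gb, loss = self._grad(X[idx], Y[idx], weights)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                    )
                gnorm = math.sqrt(float((gW**2).sum() + (gb**2).sum()))
                if config.grad_clip and gnorm > config.grad_clip:
                    scale = config.grad_clip / gnorm
                    gW = gW * scale
                    gb = gb * scale
                step += 1
                mW = beta1 * mW + (1 - beta1) * gW
                vW = beta2 * vW + (1 - beta2) * gW**2
                mb = beta1 * mb + (1 - beta1) * gb
                vb = beta2 * vb + (1 - beta2) * gb**2
                corr1 = 1 - beta1**step
                corr2 = 1 - beta2**step
                self.W -= config.learning_rate * (mW / corr1) / (
                    np.sqrt(vW / corr2) + adam_eps
                )
                self.b -= config.learning_rate * (mb / corr1) / (
                    np.sqrt(vb / corr2) + adam_eps
                )
            self.n_epochs_run = epoch + 1
            if has_val:
                score = self._val_macro_f1(val_features, val_labels)
            else:
                score = self._val_macro_f1(X_raw, labels)
            if score > best:
                best = score
                best_params = (self.W.copy(), self.b.copy())
                self.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
        self.W, self.b = best_params
        self.val_score = float(best)
        return self

    def _val_macro_f1(self, X: np.ndarray, labels: LabelMatrix) -> float:
        probs = self.predict_proba(X)
        if self.task_mode == MULTI_LABEL:
            pred = (probs.values >= 0.5).astype(np.int8)
            return macro_f1(labels, pred)
        pred_idx = probs.values.argmax(axis=1)
        pred = np.zeros((len(pred_idx), labels.n_labels), dtype=np.int8)
        pred[np.arange(len(pred_idx)), pred_idx] = 1
        return macro_f1(labels, pred)

    # -- inference --------------------------------------------------------

    def predict_logits(self, features: np.ndarray) -> np.ndarray:
        if self.W is None:
            raise RuntimeError("backbone is not fitted")
        X = self._standardize(np.asarray(features, dtype=float))
        return X @ self.W + self.b

    def predict_proba(self, features: np.ndarray) -> ProbMatrix:
        Z = self.predict_logits(features)
        if self.task_mode == MULTI_LABEL:
            return ProbMatrix(_sigmoid(Z), MULTI_LABEL)
        return ProbMatrix(_softmax(Z), MULTI_CLASS)

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "task_mode": self.task_mode,
            "W": self.W.tolist() if self.W is not None else None,
            "b": self.b.tolist() if self.b is not None else None,
            "feat_mean": None if self.feat_mean is None else self.feat_mean.tolist(),
            "feat_scale": None
            if self.feat_scale is None
            else self.feat_scale.tolist(),
            "val_score": self.val_score,
            "best_epoch": self.best_epoch,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, obj: dict) -> "LinearBackbone":
        bb = cls(obj["name"], obj["task_mode"])
        bb.W = np.array(obj["W"]) if obj["W"] is not None else None
        bb.b = np.array(obj["b"]) if obj["b"] is not None else None
        if obj.get("feat_mean") is not None:
            bb.feat_mean = np.array(obj["feat_mean"])
            bb.feat_scale = np.array(obj["feat_scale"])
        bb.val_score = obj.get("val_score", float("nan"))
        bb.best_epoch = obj.get("best_epoch", -1)
        return bb

    @classmethod
    def load(cls, path) -> "LinearBackbone":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def train_reference_backbone(
    features: np.ndarray,
    labels: LabelMatrix,
    config: TrainConfig | None = None,
    weights: ClassWeights | None = None,
    val_features: np.ndarray | None = None,
    val_labels: LabelMatrix | None = None,
    name: str = "linear",
) -> LinearBackbone:
    """Train a linear reference backbone; deterministic given the config seed."""
    bb = LinearBackbone(name, labels.task_mode)
    return bb.fit(features, labels, weights, config, val_features, val_labels)


# -- feature views --------------------------------------------------------


@dataclass
class VocabularyView:
    """Seeded vocabulary-hash filter: a token is kept with probability
    ``keep_frac`` (decided by a hash of the token and the view seed);
    dropped tokens are replaced by an UNK placeholder.  Members built on
    different view seeds see different random vocabulary subsets and hence
    excel on different label subsets."""

    seed: int
    keep_frac: float = 0.55

    def keeps(self, token: str) -> bool:
        h = hashlib.blake2b(
            f"{self.seed}:{token}".encode(), digest_size=8
        ).digest()
        return int.from_bytes(h, "big") / 2**64 < self.keep_frac

    def filter(self, tokens: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(t if self.keeps(t) else VIEW_UNK for t in tokens)


def view_features(
    corpus: Corpus, vz: HybridVectorizer, view: VocabularyView | None
) -> np.ndarray:
    """Pooled document features under an optional vocabulary view."""
    cache: dict[str, np.ndarray] = {}
    out = np.empty((len(corpus), vz.output_dim))
    for i, doc in enumerate(corpus):
        toks = doc.tokens if view is None else view.filter(doc.tokens)
        acc = np.zeros(vz.output_dim)
        for t in toks:
            vec = cache.get(t)
            if vec is None:
                vec = hybrid_vector(t, vz)
                cache[t] = vec
            acc += vec
        out[i] = acc / max(len(toks), 1)
    return out


def random_projection_view(
    features: np.ndarray, out_dim: int, seed: int
) -> np.ndarray:
    """Seeded Gaussian random projection of pooled features."""
    rng = np.random.default_rng(seed)
    X = np.asarray(features, dtype=float)
    R = rng.normal(0.0, 1.0 / np.sqrt(out_dim), size=(X.shape[1], out_dim))
    return X @ R


def write_probs_csv(path, probs: ProbMatrix, label_names: list[str]) -> None:
    """Probability exchange format: CSV with a header of label names."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(label_names) + "\n")
        for row in probs.values:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def read_probs_csv(path, task_mode: str) -> tuple[ProbMatrix, list[str]]:
    with open(path, encoding="utf-8") as fh:
        names = fh.readline().strip().split(",")
        rows = [
            [float(v) for v in line.strip().split(",")]
            for line in fh
            if line.strip()
        ]
    return ProbMatrix(np.array(rows), task_mode), names
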