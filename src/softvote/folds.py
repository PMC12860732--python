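"""Data splitting: stratified tri-splits and k-fold plans.

Two stratification regimes are provided, matching the two task modes:

* multi-class — standard stratified splitting: within each class, indices
  are shuffled and dealt proportionally, so each fold's class counts
  deviate from exact proportionality by at most 1;
* multi-label — greedy iterative stratification: labels are processed
  rarest first, and each document is assigned to the fold with the
  greatest remaining demand for that label (ties broken by overall
  remaining capacity, then seeded random).  This preserves per-label
  positive frequencies, and in particular label co-occurrence structure,
  far better than a random split.

A :class:`FoldPlan` holds, per fold, disjoint train/validation/test index
sets.  The single 80-5-15 tri-split and the k-fold protocol share the same
machinery: in k-fold mode each fold's test set is a k-th of the corpus and
a validation set is carved from the training portion at 1/16 (mirroring
the 5/80 ratio of the tri-split).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import MULTI_CLASS, MULTI_LABEL, LabelMatrix

#: validation share of the training portion in k-fold mode (= 5/80)
VAL_SHARE_OF_TRAIN = 1.0 / 16.0


@dataclass
class Fold:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.int64)
        self.val = np.asarray(self.val, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)
        sets = [set(self.train), set(self.val), set(self.test)]
        total = len(self.train) + len(self.val) + len(self.test)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/val/test sets must be disjoint")


@dataclass
class FoldPlan:
    k: int
    folds: list[Fold]
    seed: int = 0

    def to_json(self, path) -> None:
        obj = {
            "k": self.k,
            "seed": self.seed,
            "folds": [
                {
                    "train": f.train.tolist(),
                    "val": f.val.tolist(),
                    "test": f.test.tolist(),
                }
                for f in self.folds
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            k=obj["k"],
            seed=obj.get("seed", 0),
            folds=[Fold(f["train"], f["val"], f["test"]) for f in obj["folds"]],
        )


def _proportional_split(
    groups: list[np.ndarray], fractions: tuple[float, ...], rng: np.random.Generator
) -> list[list[int]]:
    """Allocate each group's (pre-shuffled) members across parts.

    Within each group, counts are floors of the proportional quotas;
    remainder units go to the part with the largest cumulative deficit
    (cumulative quota minus allocated so far), which keeps both per-group
    and global part sizes within 1 of proportionality."""
    n_parts = len(fractions)
    parts: list[list[int]] = [[] for _ in range(n_parts)]
    fr = np.asarray(fractions, dtype=float)
    cum_quota = np.zeros(n_parts)
    allocated = np.zeros(n_parts, dtype=int)
    for members in groups:
        members = members.copy()
        rng.shuffle(members)
        n = len(members)
        quotas = fr * n
        counts = np.floor(quotas).astype(int)
        cum_quota += quotas
        allocated += counts
        rem = n - counts.sum()
        for _ in range(rem):
            p = int(np.argmax(cum_quota - allocated))
            counts[p] += 1
            allocated[p] += 1
        start = 0
        for p in range(n_parts):
            parts[p].extend(members[start : start + counts[p]].tolist())
            start += counts[p]
    return parts


def _iterative_assign(
    onehot: np.ndarray,
    indices: np.ndarray,
    fractions: tuple[float, ...],
    rng: np.random.Generator,
) -> list[list[int]]:
    """Greedy iterative stratification of ``indices`` into len(fractions)
    parts with the given target shares."""
    n, c = onehot.shape
    n_parts = len(fractions)
    fr = np.asarray(fractions, dtype=float)
    counts = onehot.sum(axis=0).astype(float)
    desired = np.outer(fr, counts)  # parts x labels: remaining demand
    capacity = fr * n  # remaining overall capacity per part
    parts: list[list[int]] = [[] for _ in range(n_parts)]
    unassigned = set(range(n))

    active = [c_ for c_ in range(c) if counts[c_] > 0]
    if len(active) < c:
        warnings.warn(
            "labels with zero positives are excluded from stratification",
            stacklevel=3,
        )
    remaining = {c_: int(counts[c_]) for c_ in active}
    while remaining:
        # rarest label first (among labels with remaining unassigned docs)
        lab = min(remaining, key=lambda c_: (remaining[c_], c_))
        rows = [i for i in unassigned if onehot[i, lab]]
        for i in rows:
            demand = desired[:, lab]
            best = demand.max()
            cand = np.flatnonzero(demand >= best - 1e-12)
            if len(cand) > 1:
                caps = capacity[cand]
                cand = cand[np.flatnonzero(caps >= caps.max() - 1e-12)]
            part = int(cand[rng.integers(0, len(cand))]) if len(cand) > 1 else int(cand[0])
            parts[part].append(int(indices[i]))
            unassigned.discard(i)
            desired[part] -= onehot[i]
            capacity[part] -= 1.0
            for c_ in np.flatnonzero(onehot[i]):
                if int(c_) in remaining:
                    remaining[int(c_)] -= 1
        remaining = {c_: v for c_, v in remaining.items() if v > 0}
    # all-zero documents: fill by remaining capacity
    for i in sorted(unassigned):
        part = int(np.argmax(capacity))
        parts[part].append(int(indices[i]))
        capacity[part] -= 1.0
    return parts


def tri_split(
    labels: LabelMatrix,
    fractions: tuple[float, float, float] = (0.80, 0.05, 0.15),
    seed: int = 0,
) -> FoldPlan:
    """Single stratified train/validation/test split (default 80-5-15)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(labels)
    if labels.task_mode == MULTI_CLASS:
        groups = [
            np.flatnonzero(np.asarray(labels.values) == c)
            for c in range(labels.n_labels)
        ]
        parts = _proportional_split(groups, fractions, rng)
    else:
        parts = _iterative_assign(
            labels.one_hot(), np.arange(n), fractions, rng
        )
    fold = Fold(
        np.sort(parts[0]), np.sort(parts[1]), np.sort(parts[2])
    )
    return FoldPlan(k=1, folds=[fold], seed=seed)


def stratified_kfold(labels: LabelMatrix, k: int, seed: int = 0) -> FoldPlan:
    """Standard stratified k-fold for the multi-class task.

    Each fold's test class counts differ from exact proportionality by at
    most 1; the validation set is carved from the training portion at
    1/16, stratified the same way.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if labels.task_mode != MULTI_CLASS:
        raise ValueError("stratified_kfold requires multi-class labels")
    y = np.asarray(labels.values)
    counts = labels.positive_counts()
    low = [labels.label_names[c] for c in np.flatnonzero(counts < k)]
    if low:
        raise ValueError(f"classes with fewer than k={k} members: {low}")
    rng = np.random.default_rng(seed)
    test_sets: list[list[int]] = [[] for _ in range(k)]
    for c in range(labels.n_labels):
        members = np.flatnonzero(y == c)
        rng.shuffle(members)
        for j, idx in enumerate(members):
            test_sets[j % k].append(int(idx))
    folds = []
    for j in range(k):
        test = np.sort(test_sets[j])
        rest = np.setdiff1d(np.arange(len(y)), test)
        groups = [rest[y[rest] == c] for c in range(labels.n_labels)]
        tr, va = _proportional_split(
            groups, (1.0 - VAL_SHARE_OF_TRAIN, VAL_SHARE_OF_TRAIN), rng
        )
        folds.append(Fold(np.sort(tr), np.sort(va), test))
    return FoldPlan(k=k, folds=folds, seed=seed)


def iterative_stratified_kfold(
    labels: LabelMatrix, k: int, seed: int = 0
) -> FoldPlan:
    """Iteratively stratified k-fold for the multi-label task.

    Greedy rarest-label-first assignment balances every label's positives
    across the k test folds; per fold each label's positive count deviates
    from proportionality by at most ceil(N_c/k) - floor(N_c/k) + 1.
    Labels with fewer than k positives are split best-effort (warning).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if labels.task_mode != MULTI_LABEL:
        raise ValueError("iterative_stratified_kfold requires multi-label labels")
    onehot = labels.one_hot()
    counts = labels.positive_counts()
    low = np.flatnonzero((counts > 0) & (counts < k))
    if len(low):
        warnings.warn(
            f"labels with fewer than k={k} positives are split best-effort: "
            f"{[labels.label_names[c] for c in low]}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = len(labels)
    test_parts = _iterative_assign(
        onehot, np.arange(n), tuple([1.0 / k] * k), rng
    )
    folds = []
    for j in range(k):
        test = np.sort(np.asarray(test_parts[j], dtype=np.int64))
        rest = np.setdiff1d(np.arange(n), test)
        tr_va = _iterative_assign(
            onehot[rest],
            rest,
            (1.0 - VAL_SHARE_OF_TRAIN, VAL_SHARE_OF_TRAIN),
            rng,
        )
        folds.append(
            Fold(np.sort(tr_va[0]), np.sort(tr_va[1]), test)
        )
    return FoldPlan(k=k, folds=folds, seed=seed)


def kfold(labels: LabelMatrix, k: int, seed: int = 0) -> FoldPlan:
    """Task-mode dispatch: standard stratification for multi-class,
    iterative stratification for multi-label."""
    if labels.task_mode == MULTI_CLASS:
        return stratified_kfold(labels, k, seed)
    return iterative_stratified_kfold(labels, k, seed)


def deviation_bound(n_positives: int, k: int) -> int:
    """Per-fold deviation bound: ceil(N_c/k) - floor(N_c/k) + 1."""
    return math.ceil(n_positives / k) - math.floor(n_positives / k) + 1
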