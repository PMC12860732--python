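"""Classification metrics with epsilon-guarded denominators, and paired
fold-level statistics.

Per-class precision, recall and F1 are computed from contingency counts
with a small epsilon added to every denominator, so degenerate classes
(no predictions, no positives) yield 0 rather than NaN:

    P_c = TP_c / (TP_c + FP_c + eps)
    R_c = TP_c / (TP_c + FN_c + eps)
    F1_c = 2 P_c R_c / (P_c + R_c + eps)

Macro aggregates are unweighted class means; micro aggregates pool the
counts across classes first.  Macro-F1 is the package's primary metric:
it weighs every class equally and is therefore sensitive to minority
performance.

Fold-level model comparison uses the paired t-test on fold-wise deltas,
Cohen's d (mean delta / sample sd), Cliff's delta (all cross pairs), and
the 95% t confidence interval of the mean delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .corpus import MULTI_CLASS, LabelMatrix

DEFAULT_EPS = 1e-12


@dataclass
class ContingencyTable:
    """Per-class TP/FP/FN/TN counts accumulated over all examples."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)


def _as_binary(y: LabelMatrix | np.ndarray) -> np.ndarray:
    if isinstance(y, LabelMatrix):
        return y.one_hot()
    return np.asarray(y)


def contingency(
    y_true: LabelMatrix | np.ndarray, y_pred: LabelMatrix | np.ndarray
) -> ContingencyTable:
    """Exact per-class contingency counts.

    Multi-class inputs (LabelMatrix in multi-class mode) are one-hot
    expanded per class, so a multi-class prediction error counts as one FN
    for the true class and one FP for the predicted class.
    """
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: y_true {t.shape} vs y_pred {p.shape}")
    t = t.astype(bool)
    p = p.astype(bool)
    tp = (t & p).sum(axis=0).astype(np.int64)
    fp = (~t & p).sum(axis=0).astype(np.int64)
    fn = (t & ~p).sum(axis=0).astype(np.int64)
    tn = (~t & ~p).sum(axis=0).astype(np.int64)
    return ContingencyTable(tp, fp, fn, tn)


@dataclass
class MetricsReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    eps: float = DEFAULT_EPS

    def to_dict(self) -> dict:
        return {
            "per_class": {
                "precision": list(map(float, self.precision)),
                "recall": list(map(float, self.recall)),
                "f1": list(map(float, self.f1)),
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            },
            "eps": self.eps,
        }


def prf_report(ct: ContingencyTable, eps: float = DEFAULT_EPS) -> MetricsReport:
    """Per-class, macro and micro P/R/F1 with eps in every denominator."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    tp = ct.tp.astype(float)
    fp = ct.fp.astype(float)
    fn = ct.fn.astype(float)
    precision = tp / (tp + fp + eps)
    recall = tp / (tp + fn + eps)
    f1 = 2.0 * precision * recall / (precision + recall + eps)
    tp_mi, fp_mi, fn_mi = tp.sum(), fp.sum(), fn.sum()
    p_mi = tp_mi / (tp_mi + fp_mi + eps)
    r_mi = tp_mi / (tp_mi + fn_mi + eps)
    f_mi = 2.0 * p_mi * r_mi / (p_mi + r_mi + eps)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        micro_precision=float(p_mi),
        micro_recall=float(r_mi),
        micro_f1=float(f_mi),
        eps=eps,
    )


def macro_f1(
    y_true: LabelMatrix | np.ndarray,
    y_pred: LabelMatrix | np.ndarray,
    classes: list[int] | None = None,
    eps: float = DEFAULT_EPS,
) -> float:
    """Macro-F1, optionally restricted to a class subset (minority set)."""
    ct = contingency(y_true, y_pred)
    rep = prf_report(ct, eps)
    if classes is None:
        return rep.macro_f1
    return float(np.mean(rep.f1[np.asarray(classes, dtype=int)]))


def micro_f1(
    y_true: LabelMatrix | np.ndarray,
    y_pred: LabelMatrix | np.ndarray,
    eps: float = DEFAULT_EPS,
) -> float:
    return prf_report(contingency(y_true, y_pred), eps).micro_f1


def minority_labels(labels: LabelMatrix) -> list[int]:
    """Labels with positive rate strictly below the median positive rate."""
    rates = labels.positive_counts() / max(len(labels), 1)
    med = float(np.median(rates))
    out = [c for c, r in enumerate(rates) if r < med]
    if not out:  # all rates equal: fall back to the rarer half by index
        out = list(np.argsort(rates)[: labels.n_labels // 2])
    return out


def cliffs_delta(a: np.ndarray, b: np.ndarray) -> float:
    """Classical Cliff's delta over all cross pairs:
    (#{a_i > b_j} - #{a_i < b_j}) / (n*m)."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    gt = (a > b).sum()
    lt = (a < b).sum()
    return float((gt - lt) / (a.shape[0] * b.shape[1]))


def paired_cliffs_delta(a: np.ndarray, b: np.ndarray) -> float:
    """Paired (sign-statistic) variant over fold-wise deltas."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(((d > 0).sum() - (d < 0).sum()) / len(d))


@dataclass
class PairedComparison:
    deltas: np.ndarray
    mean_delta: float
    t_stat: float
    p_value: float
    cohens_d: float
    cliffs_delta: float
    ci95: tuple[float, float]
    degenerate: bool = False
    cliffs_variant: str = "classical"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "deltas": list(map(float, self.deltas)),
            "mean_delta": self.mean_delta,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "cohens_d": self.cohens_d,
            "cliffs_delta": self.cliffs_delta,
            "ci95": list(self.ci95),
            "degenerate": self.degenerate,
            "cliffs_variant": self.cliffs_variant,
        }


def paired_tests(
    a: np.ndarray, b: np.ndarray, paired_cliffs: bool = False
) -> PairedComparison:
    """Paired comparison of two systems' fold scores.

    Deltas are ``a - b``.  When the delta sd is zero the t statistic and
    Cohen's d are undefined: they are reported as NaN with ``degenerate``
    set, while Cliff's delta and the (degenerate) CI are still computed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("a and b must be equal-length 1-D arrays with n >= 2")
    d = a - b
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    variant = "paired" if paired_cliffs else "classical"
    delta = paired_cliffs_delta(a, b) if paired_cliffs else cliffs_delta(a, b)
    if sd == 0.0:
        return PairedComparison(
            deltas=d,
            mean_delta=mean,
            t_stat=float("nan"),
            p_value=float("nan"),
            cohens_d=float("nan"),
            cliffs_delta=delta,
            ci95=(mean, mean),
            degenerate=True,
            cliffs_variant=variant,
        )
    t_stat, p_value = sps.ttest_rel(a, b)
    se = sd / np.sqrt(n)
    crit = sps.t.ppf(0.975, n - 1)
    return PairedComparison(
        deltas=d,
        mean_delta=mean,
        t_stat=float(t_stat),
        p_value=float(p_value),
        cohens_d=mean / sd,
        cliffs_delta=delta,
        ci95=(mean - crit * se, mean + crit * se),
        degenerate=False,
        cliffs_variant=variant,
    )


def mean_ci95(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, lo, hi) of the 95% t interval of the mean."""
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    if len(v) < 2:
        return mean, mean, mean
    se = float(v.std(ddof=1)) / np.sqrt(len(v))
    crit = float(sps.t.ppf(0.975, len(v) - 1))
    return mean, float(mean - crit * se), float(mean + crit * se)
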