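"""Quantitative validation of token-level explanations.

Faithfulness is measured with deletion curves: perturb the k most
important tokens (cumulatively, k = 1..K), rescore, and record the score
drop Delta_p(k) = p^(0) - p^(k).  The area under the deletion curve,
AUC_del = mean_k Delta_p(k), summarizes faithfulness (larger = the
explanation names tokens the model actually relies on).  Sufficiency and
comprehensiveness complement it: Suff(K) is the drop when only the top-K
tokens are kept (small = the top-K suffice), Comp(K) the drop when the
top-K are masked (large = they were necessary); Comp(K) coincides exactly
with the mask-policy deletion curve at step K.

Three perturbation policies are supported: ``mask`` (replace with
``[MASK]``), ``delete`` (remove the token, sequence shrinks) and ``unk``
(replace with ``<UNK>``).  A document emptied by deletion is scored as the
single-token sequence ``[MASK]``.

Stability across explainer re-runs is measured by Overlap@K (mean
pairwise Jaccard of top-K position sets) and mean pairwise Kendall tau-b
over importance scores on the union of each pair's top-K positions
(zero-filled for positions absent from one run).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .corpus import Document
from .lime import MASK_TOKEN, Explanation, ExplainerConfig, explain
from .metrics import mean_ci95

POLICIES = ("mask", "delete", "unk")
UNK_TOKEN = "<UNK>"


def apply_policy(doc: Document, positions, policy: str) -> Document:
    """Perturb ``doc`` at ``positions`` under a policy; the input document
    is left unmodified."""
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    pos = set(int(p) for p in positions)
    for p in pos:
        if not 0 <= p < len(doc.tokens):
            raise IndexError(f"position {p} out of range for document {doc.id!r}")
    if policy == "delete":
        toks = tuple(t for i, t in enumerate(doc.tokens) if i not in pos)
    else:
        repl = MASK_TOKEN if policy == "mask" else UNK_TOKEN
        toks = tuple(
            repl if i in pos else t for i, t in enumerate(doc.tokens)
        )
    return Document(id=doc.id, raw_text=" ".join(toks), tokens=toks)


def _score_tokens(scorer, token_lists, class_index: int, basis: str) -> np.ndarray:
    lists = [toks if toks else (MASK_TOKEN,) for toks in token_lists]
    return np.asarray(scorer.score(lists, class_index, basis), dtype=float)


@dataclass
class DeletionCurve:
    class_index: int
    basis: str
    policy: str
    baseline: float
    drops: np.ndarray  # Delta_p(k), k = 1..K
    positions: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.drops)


def deletion_curve(
    doc: Document,
    scorer,
    explanation: Explanation,
    k: int,
    policy: str = "mask",
    basis: str = "probability",
) -> DeletionCurve:
    """Cumulative top-k perturbation curve.

    Positions follow the explanation's importance ranking (absolute score
    descending, ties by position); for each k the top-k set is perturbed
    together and the document rescored.
    """
    if len(explanation.scores) == 0:
        raise ValueError("explanation has no scored positions")
    ranked = explanation.ranked_positions()
    k_eff = min(k, len(ranked))
    batches = [
        apply_policy(doc, ranked[: kk + 1], policy).tokens
        for kk in range(k_eff)
    ]
    scores = _score_tokens(
        scorer, [doc.tokens] + batches, explanation.class_index, basis
    )
    baseline = float(scores[0])
    drops = baseline - scores[1:]
    return DeletionCurve(
        class_index=explanation.class_index,
        basis=basis,
        policy=policy,
        baseline=baseline,
        drops=drops,
        positions=ranked[:k_eff],
    )


def auc_del(curve: DeletionCurve) -> float:
    """Arithmetic mean of the deletion-curve drops."""
    if curve.k == 0:
        raise ValueError("empty deletion curve")
    return float(np.mean(curve.drops))


def sufficiency_comprehensiveness(
    doc: Document,
    scorer,
    explanation: Explanation,
    k: int,
    basis: str = "probability",
) -> tuple[float, float]:
    """Suff(K): drop when only the top-K tokens are kept (rest masked);
    Comp(K): drop when the top-K tokens are masked."""
    ranked = explanation.ranked_positions()
    top = set(ranked[: min(k, len(ranked))])
    rest = [i for i in range(len(doc.tokens)) if i not in top]
    keep_doc = apply_policy(doc, rest, "mask")
    drop_doc = apply_policy(doc, top, "mask")
    scores = _score_tokens(
        scorer,
        [doc.tokens, keep_doc.tokens, drop_doc.tokens],
        explanation.class_index,
        basis,
    )
    baseline = float(scores[0])
    return baseline - float(scores[1]), baseline - float(scores[2])


def overlap_at_k(runs: list[Explanation], k: int) -> float:
    """Mean pairwise Jaccard of top-K position sets across runs."""
    if len(runs) < 2:
        raise ValueError("at least two runs required")
    sets = [set(r.ranked_positions()[:k]) for r in runs]
    vals = []
    for a, b in itertools.combinations(sets, 2):
        union = a | b
        vals.append(len(a & b) / len(union) if union else 1.0)
    return float(np.mean(vals))


def kendall_stability(runs: list[Explanation], k: int | None = None) -> float:
    """Mean pairwise Kendall tau-b of token importances across runs.

    Each pair is compared on the union of the two runs' top-K positions
    (the full position set when k is None); a position absent from one
    run's top-K scores zero there.  Pairs whose union has fewer than two
    positions are skipped with a warning.
    """
    if len(runs) < 2:
        raise ValueError("at least two runs required")
    vals = []
    for a, b in itertools.combinations(runs, 2):
        if k is None:
            union = sorted(set(range(len(a.scores))) | set(range(len(b.scores))))
            sa = {i: a.scores[i] for i in range(len(a.scores))}
            sb = {i: b.scores[i] for i in range(len(b.scores))}
        else:
            ta = a.ranked_positions()[:k]
            tb = b.ranked_positions()[:k]
            union = sorted(set(ta) | set(tb))
            sa = {i: a.scores[i] for i in ta}
            sb = {i: b.scores[i] for i in tb}
        if len(union) < 2:
            warnings.warn("top-K union smaller than 2; pair skipped", stacklevel=2)
            continue
        xs = [sa.get(i, 0.0) for i in union]
        ys = [sb.get(i, 0.0) for i in union]
        tau = sps.kendalltau(xs, ys, variant="b").statistic
        if np.isnan(tau):  # constant vector: tau-b undefined, treat as 0
            tau = 0.0
        vals.append(float(tau))
    if not vals:
        raise ValueError("no comparable run pairs")
    return float(np.mean(vals))


@dataclass
class FaithfulnessReport:
    per_instance_auc: np.ndarray
    per_instance_suff: np.ndarray
    per_instance_comp: np.ndarray
    k: int
    policy: str
    basis: str

    def summary(self) -> dict:
        out = {}
        for name, vals in (
            ("auc_del", self.per_instance_auc),
            ("sufficiency", self.per_instance_suff),
            ("comprehensiveness", self.per_instance_comp),
        ):
            mean, lo, hi = mean_ci95(vals)
            out[name] = {"mean": mean, "ci95": [lo, hi]}
        out["k"] = self.k
        out["policy"] = self.policy
        out["basis"] = self.basis
        return out


@dataclass
class StabilityReport:
    n_runs: int
    k: int
    per_instance_overlap: np.ndarray
    per_instance_tau: np.ndarray
    per_instance_auc_sd: np.ndarray

    def summary(self) -> dict:
        ov_mean, ov_lo, ov_hi = mean_ci95(self.per_instance_overlap)
        tau_mean, tau_lo, tau_hi = mean_ci95(self.per_instance_tau)
        return {
            "n_runs": self.n_runs,
            "k": self.k,
            "overlap_at_k": {"mean": ov_mean, "ci95": [ov_lo, ov_hi]},
            "kendall_tau": {"mean": tau_mean, "ci95": [tau_lo, tau_hi]},
            "auc_del_sd": {"mean": float(np.mean(self.per_instance_auc_sd))},
        }


def robustness_suite(
    docs: list[Document],
    scorer,
    class_indices: list[int],
    config: ExplainerConfig,
    seeds: list[int],
    policies: tuple[str, ...] = POLICIES,
) -> tuple[FaithfulnessReport, StabilityReport, dict[str, float]]:
    """Multi-seed robustness evaluation.

    Runs the explainer once per seed per document, then aggregates
    deletion-curve faithfulness (mean, CI, per-instance SD across seeds),
    Overlap@K, Kendall tau, and a per-policy AUC_del table computed from
    each document's first-seed explanation.
    """
    if len(seeds) < 2:
        raise ValueError("at least two seeds required")
    k = config.top_k
    aucs, suffs, comps = [], [], []
    overlaps, taus, auc_sds = [], [], []
    policy_totals = {p: [] for p in policies}
    for doc, c in zip(docs, class_indices):
        runs = []
        run_aucs = []
        for seed in seeds:
            cfg = ExplainerConfig(
                n_samples=config.n_samples,
                kappa=config.kappa,
                top_k=k,
                basis=config.basis,
                ridge_lambda=config.ridge_lambda,
                mask_token=config.mask_token,
                seed=seed,
            )
            expl = explain(doc, scorer, c, cfg)
            runs.append(expl)
            run_aucs.append(
                auc_del(deletion_curve(doc, scorer, expl, k, "mask", config.basis))
            )
        aucs.append(float(np.mean(run_aucs)))
        auc_sds.append(float(np.std(run_aucs, ddof=0)))
        s, comp = sufficiency_comprehensiveness(
            doc, scorer, runs[0], k, config.basis
        )
        suffs.append(s)
        comps.append(comp)
        overlaps.append(overlap_at_k(runs, k))
        taus.append(kendall_stability(runs, k))
        for p in policies:
            policy_totals[p].append(
                auc_del(deletion_curve(doc, scorer, runs[0], k, p, config.basis))
            )
    faith = FaithfulnessReport(
        per_instance_auc=np.array(aucs),
        per_instance_suff=np.array(suffs),
        per_instance_comp=np.array(comps),
        k=k,
        policy="mask",
        basis=config.basis,
    )
    stab = StabilityReport(
        n_runs=len(seeds),
        k=k,
        per_instance_overlap=np.array(overlaps),
        per_instance_tau=np.array(taus),
        per_instance_auc_sd=np.array(auc_sds),
    )
    policy_table = {p: float(np.mean(v)) for p, v in policy_totals.items()}
    return faith, stab, policy_table
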