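"""End-to-end experiment driver and ablation harness.

The protocol mirrors the package's full method: generate (or load) a
corpus -> normalize/filter/deduplicate -> build k stratified folds ->
train one backbone per feature view on each training fold (class-weighted
loss, optional capped oversampling) -> compute validation-weighted fusion
weights -> calibrate per-class thresholds on fused validation
probabilities -> evaluate on the untouched test partition -> aggregate
fold metrics with 95% CIs and paired comparisons of the ensemble against
every single backbone.

Strict train/validation/test separation holds by construction: weights,
thresholds and early stopping see only training and validation indices;
test indices enter only the final evaluation.

The ablation harness reruns the identical protocol with a single named
component disabled (uniform fusion, no class weights, no oversampling,
fixed threshold 0.5, or one global threshold) and reports metric deltas.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import backbones as bb
from .corpus import MULTI_CLASS, MULTI_LABEL, Corpus, LabelMatrix, subset_corpus
from .embeddings import HybridVectorizer, random_table
from .folds import FoldPlan, kfold
from .fusion import (
    DEFAULT_GRID,
    FusionModel,
    calibrate_thresholds,
    compute_fusion_weights,
    decide_multiclass,
    decide_multilabel,
    fuse_probabilities,
)
from .metrics import (
    contingency,
    macro_f1,
    mean_ci95,
    minority_labels,
    paired_tests,
    prf_report,
)
from .preprocess import PreprocessConfig, deduplicate, filter_short
from .synth import GeneratorConfig, generate_corpus

ABLATIONS = (
    "uniform_fusion",
    "no_class_weights",
    "no_oversampling",
    "fixed_threshold_0.5",
    "global_threshold",
)


@dataclass
class ExperimentConfig:
    """Experiment-level settings; nested configs use the module defaults."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: bb.TrainConfig = field(default_factory=bb.TrainConfig)
    k: int = 5
    seed: int = 0
    n_members: int = 4
    member_keep_frac: float = 0.55
    embed_dim: int = 150
    use_class_weights: bool = True
    oversample_r: float | None = 0.5
    uniform_fusion: bool = False
    threshold_mode: str = "per-class"  # per-class | fixed0.5 | global
    grid: tuple[float, ...] = DEFAULT_GRID
    weight_metric: str = "val-macro-F1"
    run_preprocess: bool = True
    report_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.blake2b(blob, digest_size=8).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            obj = yaml.safe_load(fh) or {}
        return cls.from_dict(obj)

    @classmethod
    def from_dict(cls, obj: dict) -> "ExperimentConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(obj)
        if "generator" in kwargs and isinstance(kwargs["generator"], dict):
            kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
        if "preprocess" in kwargs and isinstance(kwargs["preprocess"], dict):
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "train" in kwargs and isinstance(kwargs["train"], dict):
            kwargs["train"] = bb.TrainConfig(**kwargs["train"])
        if "grid" in kwargs:
            kwargs["grid"] = tuple(kwargs["grid"])
        return cls(**kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def prepare_data(
    cfg: ExperimentConfig,
) -> tuple[Corpus, LabelMatrix, "object", HybridVectorizer]:
    """Generate, preprocess, and build the shared vectorizer."""
    corpus, labels, lexicon = generate_corpus(cfg.generator)
    if cfg.run_preprocess:
        kept, _removed = filter_short(corpus, cfg.preprocess)
        kept, _pairs = deduplicate(kept, cfg.preprocess)
        keep_ids = {d.id for d in kept}
        keep_idx = [i for i, d in enumerate(corpus) if d.id in keep_ids]
        corpus = subset_corpus(corpus, keep_idx)
        labels = labels.subset(keep_idx)
    vocab = sorted({t for d in corpus for t in d.tokens})
    table_a = random_table(vocab, cfg.embed_dim, seed=cfg.seed * 2 + 11)
    table_b = random_table(vocab, cfg.embed_dim, seed=cfg.seed * 2 + 12)
    vz = HybridVectorizer(table_a, table_b)
    return corpus, labels, lexicon, vz


def build_members(
    cfg: ExperimentConfig,
) -> list[bb.VocabularyView]:
    """One vocabulary-hash view per ensemble member."""
    return [
        bb.VocabularyView(seed=cfg.seed * 100 + m, keep_frac=cfg.member_keep_frac)
        for m in range(cfg.n_members)
    ]


def _global_threshold(fused_val, val_labels, grid) -> np.ndarray:
    best_tau, best = grid[0], -1.0
    y = val_labels.one_hot()
    for tau in grid:
        pred = (fused_val.values >= tau).astype(np.int8)
        score = macro_f1(y, pred)
        if score > best + 1e-15:
            best, best_tau = score, tau
    return np.full(fused_val.shape[1], best_tau)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full per-fold protocol and return the report bundle."""
    corpus, labels, _lexicon, vz = prepare_data(cfg)
    task_mode = labels.task_mode
    views = build_members(cfg)
    member_names = [f"member{m}" for m in range(cfg.n_members)]
    features = [bb.view_features(corpus, vz, v) for v in views]
    plan = kfold(labels, cfg.k, cfg.seed)
    minority = minority_labels(labels)

    fold_reports = []
    for fold_id, fold in enumerate(plan.folds):
        tr, va, te = fold.train, fold.val, fold.test
        y_tr = labels.subset(tr)
        y_va = labels.subset(va)
        y_te = labels.subset(te)
        tr_eff = tr
        if cfg.oversample_r is not None:
            tr_eff = bb.oversample_training_fold(
                tr, labels, cfg.oversample_r, seed=cfg.seed * 1000 + fold_id
            )
        y_tr_eff = labels.subset(tr_eff)
        # class weights reflect the effective training distribution the
        # loss actually sees (i.e. after any oversampling)
        weights = (
            bb.compute_class_weights(y_tr_eff)
            if cfg.use_class_weights
            else bb.ClassWeights.unit(labels.n_labels)
        )

        members = []
        val_probs, test_probs = [], []
        for m, name in enumerate(member_names):
            train_cfg = replace(cfg.train, seed=cfg.train.seed + 10 * fold_id + m)
            model = bb.train_reference_backbone(
                features[m][tr_eff],
                y_tr_eff,
                config=train_cfg,
                weights=weights,
                val_features=features[m][va],
                val_labels=y_va,
                name=name,
            )
            members.append(model)
            val_probs.append(model.predict_proba(features[m][va]))
            test_probs.append(model.predict_proba(features[m][te]))

        val_scores = np.array([m.val_score for m in members])
        if cfg.uniform_fusion:
            fusion_w = np.full(cfg.n_members, 1.0 / cfg.n_members)
        else:
            fusion_w = compute_fusion_weights(val_scores)
        fused_val = fuse_probabilities(val_probs, fusion_w)
        fused_test = fuse_probabilities(test_probs, fusion_w)

        taus = None
        if task_mode == MULTI_LABEL:
            if cfg.threshold_mode == "per-class":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    taus = calibrate_thresholds(fused_val, y_va, cfg.grid)
            elif cfg.threshold_mode == "fixed0.5":
                taus = np.full(labels.n_labels, 0.5)
            elif cfg.threshold_mode == "global":
                taus = _global_threshold(fused_val, y_va, cfg.grid)
            else:
                raise ValueError(f"unknown threshold_mode {cfg.threshold_mode!r}")
            ens_pred = decide_multilabel(fused_test, taus)
            ens_report = prf_report(contingency(y_te, ens_pred))
        else:
            pred_idx = decide_multiclass(fused_test)
            ens_pred = np.zeros((len(te), labels.n_labels), dtype=np.int8)
            ens_pred[np.arange(len(te)), pred_idx] = 1
            ens_report = prf_report(contingency(y_te, ens_pred))

        member_entries = {}
        for m, (name, model) in enumerate(zip(member_names, members)):
            if task_mode == MULTI_LABEL:
                if cfg.threshold_mode == "per-class":
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m_taus = calibrate_thresholds(val_probs[m], y_va, cfg.grid)
                elif cfg.threshold_mode == "fixed0.5":
                    m_taus = np.full(labels.n_labels, 0.5)
                else:
                    m_taus = _global_threshold(val_probs[m], y_va, cfg.grid)
                m_pred = decide_multilabel(test_probs[m], m_taus)
            else:
                idx = decide_multiclass(test_probs[m])
                m_pred = np.zeros((len(te), labels.n_labels), dtype=np.int8)
                m_pred[np.arange(len(te)), idx] = 1
            rep = prf_report(contingency(y_te, m_pred))
            member_entries[name] = {
                "val_score": float(model.val_score),
                "macro_f1": rep.macro_f1,
                "micro_f1": rep.micro_f1,
                "minority_macro_f1": float(np.mean(rep.f1[minority])),
            }

        fusion_model = FusionModel(
            member_names=member_names,
            weights=fusion_w,
            task_mode=task_mode,
            thresholds=taus,
            grid=cfg.grid,
            fold_id=fold_id,
        )
        entry = {
            "fold": fold_id,
            "sizes": {"train": len(tr), "val": len(va), "test": len(te)},
            "fusion_weights": fusion_w.tolist(),
            "thresholds": None if taus is None else list(map(float, taus)),
            "ensemble": {
                "macro_f1": ens_report.macro_f1,
                "micro_f1": ens_report.micro_f1,
                "minority_macro_f1": float(np.mean(ens_report.f1[minority])),
                "report": ens_report.to_dict(),
            },
            "members": member_entries,
            "fusion_model": {
                "weights": fusion_model.weights.tolist(),
                "thresholds": entry_thresholds(taus),
            },
        }
        fold_reports.append(entry)

    ens_macro = np.array([f["ensemble"]["macro_f1"] for f in fold_reports])
    best_single_macro = np.array(
        [max(m["macro_f1"] for m in f["members"].values()) for f in fold_reports]
    )
    ens_minor = np.array(
        [f["ensemble"]["minority_macro_f1"] for f in fold_reports]
    )
    best_single_minor = np.array(
        [
            max(m["minority_macro_f1"] for m in f["members"].values())
            for f in fold_reports
        ]
    )
    comparisons = {}
    if cfg.k >= 2:
        for name in member_names:
            member_macro = np.array(
                [f["members"][name]["macro_f1"] for f in fold_reports]
            )
            comparisons[name] = paired_tests(ens_macro, member_macro).to_dict()

    mean_, lo, hi = mean_ci95(ens_macro)
    report = {
        "task_mode": task_mode,
        "n_docs": len(corpus),
        "minority_labels": minority,
        "folds": fold_reports,
        "aggregate": {
            "ensemble_macro_f1": {"mean": mean_, "ci95": [lo, hi]},
            "ensemble_micro_f1": {
                "mean": float(
                    np.mean([f["ensemble"]["micro_f1"] for f in fold_reports])
                )
            },
            "ensemble_minority_macro_f1": {"mean": float(ens_minor.mean())},
            "best_single_macro_f1": {"mean": float(best_single_macro.mean())},
            "best_single_minority_macro_f1": {
                "mean": float(best_single_minor.mean())
            },
            "macro_f1_gain_pp": float(
                100.0 * (ens_macro - best_single_macro).mean()
            ),
            "minority_macro_f1_gain_pp": float(
                100.0 * (ens_minor - best_single_minor).mean()
            ),
        },
        "comparisons_vs_members": comparisons,
        "manifest": {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": _jsonable(asdict(cfg)),
        },
    }
    if cfg.report_dir:
        outdir = Path(cfg.report_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "experiment_report.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(report), fh, indent=1)
    return report


def entry_thresholds(taus):
    return None if taus is None else list(map(float, taus))


def run_ablation(cfg: ExperimentConfig, ablation: str, base_report: dict | None = None) -> dict:
    """Rerun the protocol with one component disabled; report metric deltas."""
    if ablation not in ABLATIONS:
        raise ValueError(
            f"unknown ablation {ablation!r}; valid keys: {list(ABLATIONS)}"
        )
    task_mode = cfg.generator.task_mode
    if ablation in ("fixed_threshold_0.5", "global_threshold") and task_mode == MULTI_CLASS:
        raise ValueError(f"{ablation} applies to the multi-label task only")
    if base_report is None:
        base_report = run_experiment(cfg)
    if ablation == "uniform_fusion":
        abl_cfg = replace(cfg, uniform_fusion=True)
    elif ablation == "no_class_weights":
        abl_cfg = replace(cfg, use_class_weights=False)
    elif ablation == "no_oversampling":
        abl_cfg = replace(cfg, oversample_r=None)
    elif ablation == "fixed_threshold_0.5":
        abl_cfg = replace(cfg, threshold_mode="fixed0.5")
    else:
        abl_cfg = replace(cfg, threshold_mode="global")
    abl_report = run_experiment(abl_cfg)

    def fold_vals(rep, key):
        return np.array([f["ensemble"][key] for f in rep["folds"]])

    deltas = {}
    for key in ("macro_f1", "micro_f1", "minority_macro_f1"):
        base_vals = fold_vals(base_report, key)
        abl_vals = fold_vals(abl_report, key)
        d = abl_vals - base_vals
        mean, lo, hi = mean_ci95(d)
        deltas[key] = {
            "base_mean": float(base_vals.mean()),
            "ablated_mean": float(abl_vals.mean()),
            "delta_mean": mean,
            "delta_ci95": [lo, hi],
        }
    return {"ablation": ablation, "deltas": deltas, "ablated_report": abl_report}
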