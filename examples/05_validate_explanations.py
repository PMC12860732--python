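"""Quantitative explanation validation: deletion curves, AUC_del,
sufficiency/comprehensiveness, and stability across explainer seeds.

AUC_del is the mean drop in model score after perturbing the top-k
attributed tokens (larger = more faithful).  Overlap@K and Kendall tau
measure whether repeated explainer runs agree on which tokens matter.
"""

import warnings

from softvote import ExplainerConfig
from softvote import backbones as bb
from softvote.experiment import ExperimentConfig, prepare_data
from softvote.faithfulness import robustness_suite
from softvote.folds import tri_split
from softvote.fusion import single_backbone_scorer
from softvote.synth import GeneratorConfig

warnings.filterwarnings("ignore")

cfg = ExperimentConfig(generator=GeneratorConfig(n_docs=1200, seed=4), seed=4)
corpus, labels, lexicon, vz = prepare_data(cfg)
fold = tri_split(labels, seed=4).folds[0]
feats = bb.view_features(corpus, vz, None)
model = bb.train_reference_backbone(
    feats[fold.train],
    labels.subset(fold.train),
    weights=bb.compute_class_weights(labels.subset(fold.train)),
    val_features=feats[fold.val],
    val_labels=labels.subset(fold.val),
)
scorer = single_backbone_scorer(vz, model)

onehot = labels.one_hot()
picks = [(int(i), int(onehot[i].argmax())) for i in fold.test if onehot[i].any()][:8]
docs = [corpus[i] for i, _ in picks]
classes = [c for _, c in picks]

faith, stability, by_policy = robustness_suite(
    docs,
    scorer,
    classes,
    ExplainerConfig(n_samples=3000, top_k=10, basis="logit", seed=0),
    seeds=[1, 2, 3],
)
print("faithfulness:", {k: v for k, v in faith.summary().items() if k == "auc_del"})
print("stability   :", stability.summary())
print("AUC_del by perturbation policy:", {k: round(v, 3) for k, v in by_policy.items()})

# Masking and <UNK> replacement behave similarly; hard deletion removes
# the position entirely and usually yields the largest (sharpest) drops.
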