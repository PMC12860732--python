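# softvote

Validation-weighted soft-voting ensembles for imbalanced text
classification, with a from-scratch local-surrogate (LIME-style) token
explainer and a quantitative faithfulness/stability validation suite.

## The problem

Screening short free-text posts for clinically salient signals — e.g.
which depression-related emotions a post expresses (multi-label, 8
co-occurring labels) or how severe it reads (multi-class, 4 ordinal
levels) — poses two coupled difficulties.  First, the labels are heavily
imbalanced and the rare ones (suicidal intent, severe cases) are exactly
the ones that matter, so training, splitting and thresholding must all be
minority-aware.  Second, a prediction in a clinical-adjacent setting
needs an explanation, and post-hoc token attributions are only worth
showing if they are demonstrably *faithful* (the model really relies on
the highlighted tokens) and *stable* (re-running the explainer gives the
same highlights).

`softvote` packages the full recipe, testable on synthetic corpora with
planted ground truth and no downloads:

* **Fusion.**  n probabilistic classifiers are combined by soft voting
  with static weights from each member's validation macro-F1,

      W_i = F1_i / Σ_k F1_k,        P_c(x) = Σ_i W_i · p_ic(x),

  and decisions ŷ_c = 1[P_c ≥ τ_c] (multi-label, per-class thresholds
  calibrated on validation over the grid τ ∈ {0.30, 0.35, …, 0.70}) or
  ŷ = argmax_c P_c (multi-class).  The variance identity
  Var[Σ α_m p_m] = Σ α_m² Var[p_m] + 2 Σ_{i<j} α_i α_j Cov(p_i, p_j)
  is exposed as a diagnostic of member decorrelation.
* **Imbalance recipe.**  Inverse-frequency class weights (mean 1) inside
  weighted BCE / CE losses, capped minority oversampling on training
  folds, stratified k-fold splits (iterative stratification for
  multi-label), and ε-guarded precision/recall/F1 with paired fold
  statistics (t-test, Cohen's d, Cliff's Δ, 95% CIs).
* **Explainability.**  A local surrogate fits a weighted ridge regression
  from mask indicators to the model score over S ≈ 5000 perturbations,
  kernel exp(−d²/κ²) in the number of masked tokens; validation computes
  deletion curves Δp(k) = p⁽⁰⁾ − p⁽ᵏ⁾, AUC_del = (1/K) Σ_k Δp(k),
  sufficiency/comprehensiveness, and stability across seeds (Overlap@K,
  Kendall τ-b) under mask / delete / `<UNK>` perturbation policies.

A synthetic-corpus generator plants disjoint token lexicons per label
with configurable imbalance and Gaussian-copula label co-occurrence, so
every claim above is checked against known ground truth.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from softvote import ExperimentConfig, GeneratorConfig, run_experiment

cfg = ExperimentConfig(generator=GeneratorConfig(n_docs=1500, seed=7), k=3, seed=7)
report = run_experiment(cfg)
agg = report["aggregate"]
print(round(agg["ensemble_macro_f1"]["mean"], 4))   # 0.9338
print(round(agg["best_single_macro_f1"]["mean"], 4))# 0.8716
print(round(agg["macro_f1_gain_pp"], 2))            # 6.23
print(round(agg["minority_macro_f1_gain_pp"], 2))   # 5.93
```

Four linear reference backbones are trained on complementary vocabulary
views of a 1500-document synthetic corpus (8 labels, positive rates 0.45
down to 0.05) over 3 stratified folds.  The fused ensemble reaches test
macro-F1 0.934 versus 0.872 for the best individual member — a +6.2
percentage-point gain overall and +5.9 pp on the below-median-frequency
minority labels, which is the mechanism the weighting is designed for.
`examples/` contains one short script per capability (generation,
preprocessing, training+fusion, explanation, explanation validation,
ablations); each prints the numbers it computes and what they mean.
A thin CLI mirrors the pipeline: `softvote generate | preprocess | split |
run | ablate | explain | validate-xai`.

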