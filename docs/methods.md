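# Methods

`softvote` implements, end to end and on fully synthetic data, an
imbalance-aware text-classification pipeline built around three ideas:
validation-weighted soft-voting fusion of heterogeneous probabilistic
classifiers, per-class decision-threshold calibration, and quantitative
validation of token-level post-hoc explanations.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Tasks and decision rules

Documents carry either a binary label matrix over C co-occurring labels
(multi-label mode, C=8 by default, emulating emotion-style annotation) or
a single class out of C (multi-class mode, C=4 by default, emulating
ordinal severity levels).  Given fused class probabilities P_c(x):

* multi-label: ŷ_c = 1[P_c(x) ≥ τ_c] with per-class thresholds τ_c
  (inclusive at the boundary);
* multi-class: ŷ = argmax_c P_c(x), ties to the lowest class index.

Thresholds are calibrated per class on the validation split by exhaustive
scoring of a fixed grid, 0.30 to 0.70 in steps of 0.05 (9 candidates),
maximizing that class's F1; ties resolve to the smallest τ, which favors
recall — the deliberate bias for minority-sensitive applications.  A class
with no validation positives receives the grid midpoint (0.50) with a
warning.

## Imbalance handling

Class weights are inverse class frequency, normalized to mean 1
(`w_c = C·(1/f_c)/Σ(1/f_k)`); frequency is the class share of documents
(multi-class) or the label's positive rate (multi-label).  They enter the
losses

* multi-label: weighted binary cross-entropy
  `−(1/C) Σ_c w_c [y_c log σ(z_c) + (1−y_c) log(1−σ(z_c))]`,
* multi-class: weighted cross-entropy `−w_y log softmax(z)_y`,

with probabilities clamped to [1e−12, 1−1e−12].  Minority classes can
additionally be oversampled on the training fold only, with a cap ratio r
(default 0.5): each deficient class is upsampled with replacement to
⌈r·majority⌉; in multi-label mode labels are processed rarest-first,
duplicating documents positive for the deficient label, under a total
duplication budget of 2× the fold.  The per-class sampling streams are
seeded so that the r=0.25 multiset is a sub-multiset of the r=0.5 one.
Class weights are computed on the *effective* fold (after oversampling):
the loss should describe the distribution it is trained on, and computing
them beforehand double-boosts minority classes.

A caveat the test suite states explicitly: for the bundled convex
reference backbones trained to convergence, random duplication is
equivalent in expectation to loss reweighting, so oversampling on top of
inverse-frequency weights tends to overcorrect and slightly *lowers*
minority F1 on the synthetic benchmark (duplicated minority documents are
memorized, costing precision).  The directional ablation test encoding
"removing class weights or oversampling never helps minority-macro-F1"
therefore fails for the oversampling arm on this stand-in; the benefit of
oversampling reported for fine-tuned transformer stacks rests on
non-convex minibatch dynamics this package intentionally does not model.
The cleaner property — inverse-frequency weighting raises minority-label
*recall* at τ=0.5 — holds and is tested in an off-ceiling regime
(overlapping classes, moderate L2), because at recall 1.0 no direction is
measurable.

## Splitting

An 80–5–15 train/validation/test tri-split and a k-fold protocol (default
k=5, a package convention) share one mechanism.  Multi-class splits are
standard stratified allocation (per-class shuffle, proportional rounding
with cumulative-deficit remainders; per-fold class counts within 1 of
proportionality).  Multi-label splits use greedy iterative
stratification: labels are processed rarest first, and each document goes
to the fold with the greatest remaining demand for that label, ties by
remaining capacity then seeded random.  Per fold, each label's positive
count stays within ⌈N_c/k⌉ − ⌊N_c/k⌋ + 1 of proportionality.  In k-fold
mode the validation split is carved from each training portion at 1/16,
mirroring the 5/80 ratio of the tri-split.

## Reference backbones and feature views

Ensemble members must only satisfy a contract — fit once, deterministic
`predict_proba`, a validation macro-F1 `val_score` — so externally trained
classifiers can join via the CSV probability-exchange format.  The bundled
member is a linear model (per-label logistic / multinomial) over pooled
hybrid embeddings:

* each word's vector is the concatenation of two L2-normalized component
  vectors (two independent tables; subword fallback composes the mean of
  known character 3–6-gram vectors with `<`/`>` boundary markers, then an
  UNK vector);
* a document is the mean of its token vectors;
* features are z-normalized per dimension inside the backbone (pooled
  embedding coordinates are ~1e−2 in scale and badly conditioned
  otherwise);
* training is mini-batch Adam (lr 0.05, batch 64) with L2 penalty,
  gradient clipping, and early stopping on validation macro-F1 (τ=0.5 /
  argmax), patience 5 within 60 epochs, returning the best-epoch
  parameters.  The L2 default (1e−3) is the strongest value that loses no
  validation macro-F1 in a one-dimensional sweep; stronger settings were
  preferred at ties to limit logit saturation, which otherwise degrades
  probability-scale explanations.

Heterogeneity comes from *vocabulary views*: member m sees only a seeded
hash-selected ~55% of the vocabulary (dropped tokens map to UNK).  Members
therefore observe different random subsets of every label's informative
tokens and genuinely excel on different label subsets — the
error-decorrelation that the ensemble-variance identity

    Var[Σ_m α_m p_m] = Σ_m α_m² Var[p_m] + 2 Σ_{i<j} α_i α_j Cov(p_i, p_j)

rewards (the identity is exposed as a diagnostic and tested to 1e−10).
Gaussian random-projection views are also provided; they decorrelate less
because all members share the same pooled signal.

## Fusion

Member weights are W_i = s_i / Σ_k s_k with s_i the member's validation
macro-F1 (pluggable metric; uniform weights available as an ablation).
Weights and thresholds are computed once per fold from validation data and
frozen for that fold's test partition; a canary test scrambles test labels
and asserts the fitted weights and thresholds are bit-identical.

## Explainer

The local surrogate explains one document/class pair.  S perturbations
(default 5000) mask m positions each, m uniform on {1..max(1, L−1)},
positions uniform without replacement; row 0 is the unperturbed document.
Samples are weighted by exp(−d²/κ²) with d = number of masked positions;
κ defaults to max(1, 0.25·L) (length-proportional locality) with a tuning
hook that grid-searches multipliers {0.1, 0.25, 0.5, 1} against mean
deletion-curve AUC on a validation subset.  A weighted ridge regression
(λ = 1e−6, intercept unpenalized) from mask indicators to the model score
yields per-position signed importances; top-K (K ∈ {5, 10}) by absolute
coefficient, ties to the earlier position.  Attribution is per position:
duplicated tokens get separate scores, because deletion curves operate on
positions.  The surrogate target is the class probability by default, or
the logit.

The logit is the natural scale for the bundled backbones: their logit is
nearly linear in the mask indicators, so the surrogate is well-specified
and its coefficients are reproducible across sampling seeds — the
stability levels the acceptance script measures on the planted-lexicon
fixture (20 true-positive documents, S=5000, 5 seeds) are obtained on
this basis.  On the probability basis stability is substantially lower on
this fixture: the sigmoid's curvature leaves residuals that randomize the
ranking of the deliberately exchangeable noise tokens competing for the
tail of the top-10.  Stability is therefore reported on the logit basis;
deletion-curve faithfulness defaults to the bounded probability basis.

## Explanation validation

Deletion curves perturb the top-k positions cumulatively (k = 1..K) under
a policy — mask (`[MASK]`), hard delete (sequence shrinks), or `<UNK>`
replacement — and record Δp(k) = p⁽⁰⁾ − p⁽ᵏ⁾; AUC_del is the mean drop.
Sufficiency keeps only the top-K (rest masked); comprehensiveness masks
the top-K, and coincides exactly with the mask-policy curve at step K
(asserted as an identity).  Both use the explanation's own magnitude
ranking so that this identity holds.  A document emptied by deletion is
scored as the single-token sequence `[MASK]`.  Stability across r
explainer re-runs reports Overlap@K (mean pairwise Jaccard of top-K
position sets) and mean pairwise Kendall τ-b over importance scores on
the union of each pair's top-K positions, zero-filled for absent
positions (τ-b because surrogate scores tie at zero).

## Synthetic corpus generator

Each label owns a disjoint lexicon (default 6 tokens); a positive label
emits each of its tokens independently with `signal_prob` (default 0.5);
remaining positions (document lengths uniform on 15–50 tokens) are filled
from a 300-token Zipf(1.1) noise vocabulary, and positions are shuffled so
the explainer faces no positional confound.  Default multi-label positive
rates fall from 0.45 to 0.05 across 8 labels (skewed-frequency,
minority-at-5% structure); the multi-class default mixture is
(0.44, 0.02, 0.45, 0.09).  Label co-occurrence is induced by a Gaussian
copula: latent scores from N(0, R) thresholded at each label's base-rate
quantile, giving exact marginals with continuous association control.

What passing tests show — and do not.  The generator gives every stage a
known ground truth: planted positions for attribution recovery, exact
label statistics for stratification audits, controllable imbalance for
the weighting/fusion directionals.  It deliberately omits syntax,
polysemy, register, correlated/ambiguous evidence and annotation noise;
tokens are opaque symbols.  Results on it validate the *machinery*
(exactness of metrics and curves, optimality of calibration, determinism,
directional behavior of fusion), not performance on real clinical text.

## Preprocessing

Normalization lowercases, strips HTML tags (sparing the package's own
placeholder tokens), replaces URLs/<USER> mentions/numeric tokens with
placeholders, maps a small emoticon table (`:)` → `<SMILE>`, `:(` →
`<SAD>`, common Unicode faces; unknown emoji kept), collapses whitespace
and tokenizes on it; it is total and idempotent.  Documents with fewer
than 20 non-whitespace characters or fewer than 3 tokens are discarded.
Near-duplicates are removed with 128-permutation MinHash over width-3 word
shingles, LSH banding for candidates, a 0.05 slack band for estimation
error, and *exact* shingle-Jaccard verification of every candidate against
the hard 0.9 threshold; the later document of a confirmed pair is dropped
(keep-earlier is a package convention; either member could equally be
retained).

## Statistics

Per-class P/R/F1 use ε-guarded denominators (ε = 1e−12, always on — at
that magnitude it is numerically indistinguishable from "only when
needed" and simpler to verify).  Macro = unweighted class mean; micro =
pooled counts.  Paired fold comparisons report the paired t-test, Cohen's
d (sample sd), classical all-cross-pairs Cliff's Δ (a paired sign-variant
is available behind a flag), and the 95% t interval; a zero-sd delta
vector flags t and d as undefined rather than fabricating values.
"Minority labels" default to those below the median positive rate.

## Problem sizes

The bundled experiments run at desk scale, chosen as the package's own
benchmark conditions: stability and recovery on an N=2000 corpus with 20
explained documents at S=5000 and 5 seeds; the ensemble-gain benchmark at
N=4000, C=8, 5 folds, four members; directional ablations at N=2000, k=3,
10 seeds.  On one CPU the full test suite runs in about three minutes and
`scripts/acceptance.py` in well under a minute.

## Known limitations

* The reference backbones are linear; conclusions about oversampling and
  about explanation difficulty transfer only partially to non-convex
  encoders (see the imbalance caveat above).
* Probability-basis attribution stability is intrinsically limited on
  corpora whose non-signal tokens are exchangeable by construction.
* MinHash candidate generation is probabilistic; a pair can in principle
  evade banding (the exact-verification step never *wrongly drops*,
  it can only miss), with vanishing probability at Jaccard ≥ 0.9.
* No grouping structure (author/thread) exists in the synthetic corpora,
  so group-aware splitting is out of scope.
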