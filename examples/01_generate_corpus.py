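"""Generate a synthetic planted-lexicon corpus and inspect its structure.

Each label owns a disjoint set of signal tokens; positive documents emit
them with probability `signal_prob`.  The printed statistics show the
skewed per-label positive rates the generator was asked for.
"""

import numpy as np

from softvote import GeneratorConfig, generate_corpus

config = GeneratorConfig(n_docs=1000, n_labels=8, seed=0)
corpus, labels, lexicon = generate_corpus(config)

print(f"{len(corpus)} documents, {labels.n_labels} labels")
rates = labels.positive_counts() / len(labels)
for name, rate, target in zip(labels.label_names, rates, config.label_base_rates):
    print(f"  {name}: positive rate {rate:.3f} (target {target:.2f})")

doc = corpus[0]
row = labels.one_hot()[0]
print(f"\nfirst document ({doc.id}), labels {np.flatnonzero(row).tolist()}:")
print(" ", " ".join(doc.tokens[:12]), "...")
print("  planted tokens of label 0:", sorted(lexicon.tokens[0])[:3], "...")

# Empirical rates track the configured base rates; every signal token in a
# document betrays one of its positive labels — that is the ground truth
# the explainer is later scored against.
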