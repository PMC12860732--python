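"""Normalize raw social-media-style text and deduplicate a tiny corpus.

Shows placeholder substitution (<URL>, <USER>, <NUM>, <SMILE>), the
minimum-length filter, and MinHash near-duplicate removal with exact
Jaccard verification.
"""

from softvote import normalize_text
from softvote.corpus import Corpus, Document
from softvote.preprocess import deduplicate, filter_short

doc = normalize_text("Check https://example.org @friend I slept 3 hours :(")
print("normalized tokens:", doc.tokens)

docs = [
    Document("a", "", tuple(f"tok{i}" for i in range(30))),
    Document("b", "", tuple(f"tok{i}" for i in range(30))),  # exact duplicate
    Document("c", "", tuple(f"other{i}" for i in range(30))),
    Document("d", "", ("too", "short")),
]
kept, removed = filter_short(Corpus(docs))
print("removed as too short:", removed)
deduped, pairs = deduplicate(kept)
for kept_id, dropped_id, jac in pairs:
    print(f"dropped {dropped_id} (near-duplicate of {kept_id}, Jaccard {jac:.2f})")
print("surviving ids:", deduped.ids())

# The duplicate 'b' is dropped (Jaccard 1.0 with 'a'); 'd' fails the
# 20-character / 3-token rule; everything else survives.
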