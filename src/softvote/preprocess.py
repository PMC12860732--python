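"""Transformer-friendly text normalization, length filtering and
near-duplicate removal.

The normalization pipeline lowercases, strips HTML tags, replaces platform
artifacts with placeholder tokens (``http(s)`` links -> ``<URL>``, user
mentions ``@handle`` / ``u/handle`` -> ``<USER>``, numeric tokens ->
``<NUM>``), maps common emoticons to sentiment placeholders (``:)`` ->
``<SMILE>``), collapses whitespace and tokenizes on whitespace.  It is a
total, idempotent function of the raw string.

Very short posts carry too little signal: documents with fewer than 20
non-whitespace characters or fewer than three tokens are discarded.

Near-duplicates are removed with MinHash over word shingles: signatures
propose candidate pairs (LSH banding), candidates are verified with the
exact shingle Jaccard, and of any pair at or above the Jaccard threshold
(default 0.9) the later document in corpus order is dropped.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document

#: Default emoticon -> placeholder table.  The pipeline names only the
#: <SMILE>/<SAD> placeholders; unknown emoji are kept as-is.
DEFAULT_EMOJI_MAP: dict[str, str] = {
    ":)": "<SMILE>",
    ":-)": "<SMILE>",
    ":d": "<SMILE>",
    "=)": "<SMILE>",
    "☺": "<SMILE>",
    "\U0001f600": "<SMILE>",
    "\U0001f642": "<SMILE>",
    "\U0001f60a": "<SMILE>",
    ":(": "<SAD>",
    ":-(": "<SAD>",
    ":'(": "<SAD>",
    "=(": "<SAD>",
    "☹": "<SAD>",
    "\U0001f641": "<SAD>",
    "\U0001f622": "<SAD>",
    "\U0001f62d": "<SAD>",
}

_URL_RE = re.compile(r"https?://\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"(?<![\w@])(?:@|u/)\w+")
# Tokens made entirely of digits with optional . , % signs count as numbers;
# alphanumeric handles are left alone.
_NUM_RE = re.compile(r"^[\d.,%]*\d[\d.,%]*$")
_WS_RE = re.compile(r"\s+")


@dataclass
class PreprocessConfig:
    min_chars: int = 20
    min_tokens: int = 3
    jaccard_threshold: float = 0.9
    shingle_width: int = 3
    minhash_perms: int = 128
    #: candidate slack below the exact threshold, to cover MinHash
    #: estimation error before exact verification
    candidate_slack: float = 0.05
    emoji_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_EMOJI_MAP))

    def __post_init__(self) -> None:
        if not 0.0 < self.jaccard_threshold <= 1.0:
            raise ValueError("jaccard_threshold must lie in (0, 1]")
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")
        if self.shingle_width < 1:
            raise ValueError("shingle_width must be >= 1")
        if self.minhash_perms < 8:
            raise ValueError("minhash_perms must be >= 8")


def _placeholder_names(emoji_map: dict[str, str]) -> set[str]:
    names = {"URL", "USER", "NUM"}
    for v in emoji_map.values():
        m = re.fullmatch(r"<([A-Za-z]+)>", v)
        if m:
            names.add(m.group(1).upper())
    return names


def normalize_text(
    raw: str,
    emoji_map: dict[str, str] | None = None,
    doc_id: str = "",
) -> Document:
    """Normalize a raw string into a tokenized :class:`Document`.

    Total function: any string (including empty) is accepted.  Idempotent
    on its own output (placeholders survive a second pass).
    """
    emoji_map = DEFAULT_EMOJI_MAP if emoji_map is None else emoji_map
    names = _placeholder_names(emoji_map)
    name_alt = "|".join(sorted(names))
    # Strip HTML tags but never the package's own placeholder tokens.
    tag_re = re.compile(rf"<(?!(?:{name_alt})>)[^<>]+>", re.IGNORECASE)

    s = raw.lower()
    s = _URL_RE.sub(" <URL> ", s)
    s = tag_re.sub(" ", s)
    s = _MENTION_RE.sub(" <USER> ", s)
    emoji_lower = {k.lower(): v for k, v in emoji_map.items()}
    tokens: list[str] = []
    for tok in _WS_RE.split(s.strip()):
        if not tok:
            continue
        m = re.fullmatch(r"<([a-z]+)>", tok)
        if m and m.group(1).upper() in names:
            tokens.append(f"<{m.group(1).upper()}>")
        elif tok in emoji_lower:
            tokens.append(emoji_lower[tok])
        elif _NUM_RE.match(tok):
            tokens.append("<NUM>")
        else:
            tokens.append(tok)
    return Document(id=doc_id, raw_text=" ".join(tokens), tokens=tuple(tokens))


def normalize_corpus(corpus: Corpus, config: PreprocessConfig | None = None) -> Corpus:
    emoji_map = (config or PreprocessConfig()).emoji_map
    return Corpus(
        [normalize_text(d.raw_text, emoji_map, doc_id=d.id) for d in corpus]
    )


def filter_short(
    corpus: Corpus, config: PreprocessConfig | None = None
) -> tuple[Corpus, list[str]]:
    """Keep documents with >= min_chars non-whitespace chars AND >= min_tokens
    tokens; report removed ids in corpus order."""
    config = config or PreprocessConfig()
    kept: list[Document] = []
    removed: list[str] = []
    for doc in corpus:
        n_chars = sum(len(t) for t in doc.tokens)
        if n_chars >= config.min_chars and len(doc.tokens) >= config.min_tokens:
            kept.append(doc)
        else:
            removed.append(doc.id)
    return Corpus(kept), removed


def shingles(doc: Document, width: int) -> set[str]:
    """Word shingles of the document; a document shorter than ``width`` is
    one shingle of its full token sequence."""
    toks = doc.tokens
    if len(toks) <= width:
        return {" ".join(toks)}
    return {" ".join(toks[i : i + width]) for i in range(len(toks) - width + 1)}


def exact_jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


_MERSENNE = (1 << 61) - 1


def _shingle_hash(s: str) -> int:
    return int.from_bytes(hashlib.blake2b(s.encode(), digest_size=8).digest(), "big")


def minhash_signatures(
    shingle_sets: list[set[str]], n_perms: int, seed: int = 12345
) -> np.ndarray:
    """MinHash signatures (n_docs x n_perms) via universal hashing
    h_i(x) = (a_i * x + b_i) mod p with a fixed internal seed, so
    signatures are reproducible across runs."""
    rng = np.random.default_rng(seed)
    a = rng.integers(1, _MERSENNE, size=n_perms, dtype=np.uint64)
    b = rng.integers(0, _MERSENNE, size=n_perms, dtype=np.uint64)
    a_obj = a.astype(object)
    b_obj = b.astype(object)
    sigs = np.full((len(shingle_sets), n_perms), np.iinfo(np.uint64).max, dtype=np.uint64)
    for i, ss in enumerate(shingle_sets):
        if not ss:
            continue
        xs = np.array([_shingle_hash(s) % _MERSENNE for s in ss], dtype=object)
        # (a*x + b) mod p in exact integer arithmetic (a*x exceeds uint64)
        hashed = (a_obj[:, None] * xs[None, :] + b_obj[:, None]) % _MERSENNE
        sigs[i] = hashed.min(axis=1).astype(np.uint64)
    return sigs


def _candidate_pairs(sigs: np.ndarray, n_bands: int = 16) -> set[tuple[int, int]]:
    n_docs, n_perms = sigs.shape
    rows = n_perms // n_bands
    pairs: set[tuple[int, int]] = set()
    for band in range(n_bands):
        block = sigs[:, band * rows : (band + 1) * rows]
        buckets: dict[bytes, list[int]] = {}
        for i in range(n_docs):
            buckets.setdefault(block[i].tobytes(), []).append(i)
        for members in buckets.values():
            for j in range(len(members)):
                for k in range(j + 1, len(members)):
                    pairs.add((members[j], members[k]))
    return pairs


def deduplicate(
    corpus: Corpus, config: PreprocessConfig | None = None
) -> tuple[Corpus, list[tuple[str, str, float]]]:
    """Remove near-duplicates at exact shingle Jaccard >= threshold.

    MinHash signatures propose candidate pairs; each candidate is verified
    with the exact Jaccard of its shingle sets, and only verified pairs at
    or above the threshold drop a document (the later one in corpus order).
    Returns the deduplicated corpus and a report of
    ``(kept_id, dropped_id, jaccard)`` pairs.
    """
    config = config or PreprocessConfig()
    n = len(corpus)
    if n < 2:
        return Corpus(list(corpus.docs)), []
    shingle_sets = [shingles(d, config.shingle_width) for d in corpus]
    sigs = minhash_signatures(shingle_sets, config.minhash_perms)
    candidates = _candidate_pairs(sigs)
    # estimated-Jaccard screen with slack, then exact verification
    est_floor = max(0.0, config.jaccard_threshold - config.candidate_slack)
    dropped: dict[int, tuple[int, float]] = {}
    for i, j in sorted(candidates):
        if j in dropped or i in dropped:
            continue
        est = float((sigs[i] == sigs[j]).mean())
        if est < est_floor:
            continue
        jac = exact_jaccard(shingle_sets[i], shingle_sets[j])
        if jac >= config.jaccard_threshold:
            dropped[j] = (i, jac)
    kept_docs = [d for idx, d in enumerate(corpus) if idx not in dropped]
    report = [
        (corpus[i].id, corpus[j].id, jac)
        for j, (i, jac) in sorted(dropped.items())
    ]
    return Corpus(kept_docs), report


def duplicate_report_csv(path, report: list[tuple[str, str, float]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kept_id,dropped_id,jaccard\n")
        for kept, droppedid, jac in report:
            fh.write(f"{kept},{droppedid},{jac:.6f}\n")
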