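"""Hybrid word representations and document pooling.

A :class:`HybridVectorizer` concatenates two word-vector tables (e.g. a
global co-occurrence table and a subword-aware table) into a single hybrid
vector per word: each component is fetched from its word table, falling
back to subword n-gram composition and finally to an UNK vector, then
L2-normalized before concatenation (a 300+300 setup yields the standard
600-dim hybrid vector).

Subword composition represents a word as the mean of the vectors of its
character n-grams (with ``<`` and ``>`` boundary markers), so
out-of-vocabulary words still receive informative vectors.  Documents are
represented by mean-pooling the hybrid vectors of their tokens.

Vector tables read/write a plain-text ``word v1 v2 ...`` format; synthetic
tables with seeded Gaussian entries are provided for experiments that need
no pretrained download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document


def character_ngrams(word: str, n_range: tuple[int, int]) -> list[str]:
    """Character n-grams of ``<word>`` for n in ``n_range`` (inclusive)."""
    marked = f"<{word}>"
    lo, hi = n_range
    return [
        marked[i : i + n]
        for n in range(lo, hi + 1)
        for i in range(len(marked) - n + 1)
    ]


@dataclass
class EmbeddingTable:
    """A word-vector table with optional subword n-gram vectors.

    All vectors share dimension ``dim``; words absent from both tables map
    to ``unk_vector``.
    """

    word_vectors: dict[str, np.ndarray]
    ngram_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    n_range: tuple[int, int] = (3, 6)
    unk_vector: np.ndarray | None = None
    dim: int = 0

    def __post_init__(self) -> None:
        if self.n_range[0] < 2:
            raise ValueError("n_range minimum must be >= 2")
        if not self.dim:
            probe = next(iter(self.word_vectors.values()), None)
            if probe is None:
                probe = next(iter(self.ngram_vectors.values()), None)
            if probe is None and self.unk_vector is None:
                raise ValueError("cannot infer dimension from an empty table")
            self.dim = len(probe if probe is not None else self.unk_vector)
        if self.unk_vector is None:
            self.unk_vector = np.zeros(self.dim)
        self.unk_vector = np.asarray(self.unk_vector, dtype=float)
        if len(self.unk_vector) != self.dim:
            raise ValueError("unk_vector dimension mismatch")

    def lookup(self, word: str) -> np.ndarray:
        """Word vector with subword fallback, then UNK fallback."""
        vec = self.word_vectors.get(word)
        if vec is not None:
            return np.asarray(vec, dtype=float)
        if self.ngram_vectors:
            return compose_subword_vector(word, self)
        return self.unk_vector


def compose_subword_vector(word: str, table: EmbeddingTable) -> np.ndarray:
    """Mean of the vectors of the word's known character n-grams.

    w = (1/|N(w)|) * sum_{g in N(w)} g over the n-grams present in the
    table; falls back to the table's UNK vector when none are known.
    """
    if not word:
        raise ValueError("word must be non-empty")
    known = [
        table.ngram_vectors[g]
        for g in character_ngrams(word, table.n_range)
        if g in table.ngram_vectors
    ]
    if not known:
        return table.unk_vector
    return np.mean(np.asarray(known, dtype=float), axis=0)


def l2_normalize(vec: np.ndarray) -> np.ndarray:
    """Unit-norm copy of ``vec``; the zero vector is left as zero."""
    norm = float(np.linalg.norm(vec))
    if norm == 0.0:
        return np.asarray(vec, dtype=float)
    return np.asarray(vec, dtype=float) / norm


@dataclass
class HybridVectorizer:
    """Concatenation of two L2-normalized component embeddings."""

    table_a: EmbeddingTable
    table_b: EmbeddingTable

    @property
    def output_dim(self) -> int:
        return self.table_a.dim + self.table_b.dim

    def __call__(self, word: str) -> np.ndarray:
        return hybrid_vector(word, self)


def hybrid_vector(word: str, vz: HybridVectorizer) -> np.ndarray:
    """Hybrid vector: L2-normalized component vectors, concatenated."""
    if not word:
        raise ValueError("word must be non-empty")
    a = l2_normalize(vz.table_a.lookup(word))
    b = l2_normalize(vz.table_b.lookup(word))
    return np.concatenate([a, b])


def pool_document(doc: Document, vz: HybridVectorizer) -> np.ndarray:
    """Mean of the hybrid vectors over the document's tokens.

    Fully-OOV tokens contribute the concatenated UNK vectors; an empty
    document is an error (filtered upstream by the length filter).
    """
    if len(doc.tokens) == 0:
        raise ValueError(f"cannot pool empty document {doc.id!r}")
    mat = np.stack([hybrid_vector(t, vz) for t in doc.tokens])
    return mat.mean(axis=0)


def pool_corpus(corpus: Corpus, vz: HybridVectorizer) -> np.ndarray:
    """N x output_dim matrix of pooled document vectors (cached per token)."""
    cache: dict[str, np.ndarray] = {}
    out = np.empty((len(corpus), vz.output_dim))
    for i, doc in enumerate(corpus):
        if len(doc.tokens) == 0:
            raise ValueError(f"cannot pool empty document {doc.id!r}")
        acc = np.zeros(vz.output_dim)
        for t in doc.tokens:
            vec = cache.get(t)
            if vec is None:
                vec = hybrid_vector(t, vz)
                cache[t] = vec
            acc += vec
        out[i] = acc / len(doc.tokens)
    return out


def random_table(
    vocab: list[str],
    dim: int,
    seed: int,
    with_ngrams: bool = False,
    n_range: tuple[int, int] = (3, 6),
) -> EmbeddingTable:
    """Synthetic embedding table with seeded Gaussian entries.

    Entries are N(0, 1/sqrt(dim)); with ``with_ngrams`` the character
    n-grams of the vocabulary also receive vectors, enabling subword
    composition for unseen words.
    """
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(dim)
    words = {w: rng.normal(0.0, scale, size=dim) for w in sorted(set(vocab))}
    ngrams: dict[str, np.ndarray] = {}
    if with_ngrams:
        grams = sorted({g for w in words for g in character_ngrams(w, n_range)})
        ngrams = {g: rng.normal(0.0, scale, size=dim) for g in grams}
    unk = rng.normal(0.0, scale, size=dim)
    return EmbeddingTable(words, ngrams, n_range=n_range, unk_vector=unk, dim=dim)


def write_table(path, table: EmbeddingTable) -> None:
    """Write word vectors in plain-text ``word v1 v2 ...`` format."""
    with open(path, "w", encoding="utf-8") as fh:
        for word in sorted(table.word_vectors):
            vals = " ".join(f"{v:.6g}" for v in table.word_vectors[word])
            fh.write(f"{word} {vals}\n")


def read_table(path, n_range: tuple[int, int] = (3, 6)) -> EmbeddingTable:
    """Read a plain-text ``word v1 v2 ...`` vector table."""
    words: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            words[parts[0]] = np.array([float(v) for v in parts[1:]])
    return EmbeddingTable(words, n_range=n_range)
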