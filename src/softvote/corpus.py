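"""Core containers: tokenized documents, corpora, and label matrices.

A :class:`Corpus` is an ordered collection of :class:`Document` objects with
unique ids.  Labels live in a :class:`LabelMatrix`, which covers both task
modes used throughout the package:

* ``"multi-label"`` — an N x C binary matrix; a document may carry any
  number of labels (including none).
* ``"multi-class"`` — a length-N vector of 0-based class indices; every
  document carries exactly one class.

Corpora serialize to JSON lines (one object per document, fields ``id``,
``text`` and ``labels``) with a sidecar header record carrying the label
names and task mode, so a corpus+labels pair round-trips through a single
plain-text file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

MULTI_LABEL = "multi-label"
MULTI_CLASS = "multi-class"
TASK_MODES = (MULTI_LABEL, MULTI_CLASS)


@dataclass(frozen=True)
class Document:
    """A tokenized document with a stable id."""

    id: str
    raw_text: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """An ordered collection of documents with unique ids."""

    docs: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.id for d in self.docs]
        if len(set(ids)) != len(ids):
            raise ValueError("document ids must be unique within a corpus")

    def __len__(self) -> int:
        return len(self.docs)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.docs)

    def __getitem__(self, i: int) -> Document:
        return self.docs[i]

    def ids(self) -> list[str]:
        return [d.id for d in self.docs]


@dataclass
class LabelMatrix:
    """Ground-truth labels for a corpus, in either task mode.

    ``values`` is an ``(N, C)`` 0/1 integer array in multi-label mode, or a
    length-``N`` integer vector of 0-based class indices in multi-class
    mode.
    """

    task_mode: str
    label_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.task_mode not in TASK_MODES:
            raise ValueError(f"unknown task_mode {self.task_mode!r}")
        self.values = np.asarray(self.values)
        c = len(self.label_names)
        if self.task_mode == MULTI_LABEL:
            if self.values.ndim != 2 or self.values.shape[1] != c:
                raise ValueError("multi-label values must be N x C")
            bad = ~np.isin(self.values, (0, 1))
            if bad.any():
                raise ValueError("multi-label entries must be 0 or 1")
            self.values = self.values.astype(np.int8)
        else:
            if self.values.ndim != 1:
                raise ValueError("multi-class values must be a 1-D vector")
            if self.values.size and (
                self.values.min() < 0 or self.values.max() >= c
            ):
                raise ValueError("class indices must lie in [0, C)")
            self.values = self.values.astype(np.int64)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def __len__(self) -> int:
        return self.values.shape[0]

    def one_hot(self) -> np.ndarray:
        """Binary N x C view of the labels (identity in multi-label mode)."""
        if self.task_mode == MULTI_LABEL:
            return np.asarray(self.values, dtype=np.int8)
        out = np.zeros((len(self), self.n_labels), dtype=np.int8)
        out[np.arange(len(self)), self.values] = 1
        return out

    def positive_counts(self) -> np.ndarray:
        return self.one_hot().sum(axis=0).astype(np.int64)

    def subset(self, indices: Sequence[int]) -> "LabelMatrix":
        idx = np.asarray(indices, dtype=np.int64)
        return LabelMatrix(self.task_mode, list(self.label_names), self.values[idx])


def subset_corpus(corpus: Corpus, indices: Sequence[int]) -> Corpus:
    return Corpus([corpus.docs[i] for i in indices])


def write_jsonl(path, corpus: Corpus, labels: LabelMatrix | None = None) -> None:
    """Write a corpus (and optionally its labels) as JSON lines.

    The first line is a header record with the label names and task mode.
    """
    with open(path, "w", encoding="utf-8") as fh:
        header = {"record": "header"}
        if labels is not None:
            header["label_names"] = labels.label_names
            header["task_mode"] = labels.task_mode
        fh.write(json.dumps(header) + "\n")
        for i, doc in enumerate(corpus):
            obj = {"id": doc.id, "text": doc.raw_text}
            if labels is not None:
                if labels.task_mode == MULTI_LABEL:
                    row = labels.values[i]
                    obj["labels"] = [
                        name for name, v in zip(labels.label_names, row) if v
                    ]
                else:
                    obj["labels"] = labels.label_names[int(labels.values[i])]
            fh.write(json.dumps(obj) + "\n")


def read_jsonl(path) -> tuple[Corpus, LabelMatrix | None]:
    """Read a corpus written by :func:`write_jsonl`.

    Documents are re-tokenized by whitespace from their ``text`` field.
    Returns ``(corpus, labels)``; ``labels`` is None when the header carries
    no label names.
    """
    docs: list[Document] = []
    rows: list = []
    label_names: list[str] | None = None
    task_mode: str | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if obj.get("record") == "header":
                label_names = obj.get("label_names")
                task_mode = obj.get("task_mode")
                continue
            text = obj["text"]
            docs.append(Document(obj["id"], text, tuple(text.split())))
            rows.append(obj.get("labels"))
    corpus = Corpus(docs)
    if label_names is None or task_mode is None:
        return corpus, None
    index = {name: j for j, name in enumerate(label_names)}
    if task_mode == MULTI_LABEL:
        values = np.zeros((len(docs), len(label_names)), dtype=np.int8)
        for i, row in enumerate(rows):
            for name in row or []:
                values[i, index[name]] = 1
    else:
        values = np.array([index[r] for r in rows], dtype=np.int64)
    return corpus, LabelMatrix(task_mode, label_names, values)
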