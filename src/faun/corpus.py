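"""Gene-document collections: ingestion, tokenization and count matrices.

A *gene document* is the concatenation of all titles and abstracts
associated with one gene; a collection of them is turned into a sparse
term-by-document count matrix from which the log-entropy weighted matrix
and the NMF model are built.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "GeneDocument",
    "Vocabulary",
    "CountMatrix",
    "InvalidCollectionError",
    "tokenize",
    "split_sentences",
    "build_count_matrix",
    "rank_sentences",
    "read_collection",
    "read_stoplist",
]

# Hyphens and underscores are valid token characters; every other
# punctuation character (and whitespace) separates tokens.
_TOKEN_RE = re.compile(r"[a-z0-9_-]+")
_SENTENCE_RE = re.compile(r"(?<=[.?!])\s+")

EXPRESSION_VALUES = ("none", "up", "down")


class InvalidCollectionError(ValueError):
    """Raised when a document collection cannot yield a valid count matrix."""


def tokenize(text: str) -> list[str]:
    """Lowercase *text* and split it into terms.

    Characters outside ``[a-z0-9_-]`` act as separators, so gene symbols
    such as ``nf-kappab`` or ``ube3a`` survive as single tokens.
    """
    return _TOKEN_RE.findall(text.lower())


def split_sentences(text: str) -> list[str]:
    """Split on sentence-final punctuation (``.?!``) followed by whitespace."""
    parts = _SENTENCE_RE.split(text.strip())
    return [p for p in parts if p]


@dataclass
class GeneDocument:
    """One gene's concatenated literature text.

    Parameters
    ----------
    gene_id:
        Unique symbol naming the gene (and the document).
    text:
        Raw document string (concatenated titles and abstracts).
    classes:
        Optional set of category labels for evaluation.
    expression:
        Optional microarray direction: ``"up"``, ``"down"`` or ``"none"``.
    """

    gene_id: str
    text: str
    classes: frozenset[str] | None = None
    expression: str = "none"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.expression not in EXPRESSION_VALUES:
            raise ValueError(
                f"expression must be one of {EXPRESSION_VALUES}, got {self.expression!r}"
            )
        if self.classes is not None:
            self.classes = frozenset(self.classes)

    @property
    def sentences(self) -> list[str]:
        """Sentence segmentation of :attr:`text` (derived, not stored)."""
        return split_sentences(self.text)


@dataclass
class Vocabulary:
    """Ordered dictionary of retained terms with their frequencies."""

    terms: list[str]
    global_freq: np.ndarray  # total count of each term over the collection
    doc_freq: np.ndarray  # number of documents containing each term

    def __post_init__(self) -> None:
        self.global_freq = np.asarray(self.global_freq, dtype=np.int64)
        self.doc_freq = np.asarray(self.doc_freq, dtype=np.int64)
        if not (len(self.terms) == len(self.global_freq) == len(self.doc_freq)):
            raise ValueError("terms, global_freq and doc_freq must align")
        if any(self.terms[i] >= self.terms[i + 1] for i in range(len(self.terms) - 1)):
            raise ValueError("terms must be unique and lexicographically sorted")
        if len(self.terms) and not np.all(self.global_freq >= self.doc_freq):
            raise ValueError("global_freq must be >= doc_freq")
        if len(self.terms) and not np.all(self.doc_freq >= 1):
            raise ValueError("every retained term must occur in >= 1 document")

    def __len__(self) -> int:
        return len(self.terms)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


@dataclass
class CountMatrix:
    """Sparse m×n term-by-gene-document matrix of raw frequencies f_ij."""

    counts: sparse.csr_matrix
    vocabulary: Vocabulary
    doc_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        m, n = self.counts.shape
        if m != len(self.vocabulary):
            raise ValueError("row count must equal vocabulary size")
        if n != len(self.doc_ids):
            raise ValueError("column count must equal number of doc_ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def build_count_matrix(
    docs: Sequence[GeneDocument],
    stoplist: Iterable[str] = (),
    min_global: int = 2,
) -> CountMatrix:
    """Build the term-by-document count matrix for a collection.

    Stoplist terms are removed, and a term is retained only if its total
    count over the whole collection is at least ``min_global`` (default 2:
    hapax terms carry no co-occurrence signal).

    Raises
    ------
    InvalidCollectionError
        If fewer than two documents are given, if no term survives, or if
        some document loses every term to the filters.
    """
    if len(docs) < 2:
        raise InvalidCollectionError(
            f"a collection needs >= 2 documents, got {len(docs)}"
        )
    ids = [d.gene_id for d in docs]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise InvalidCollectionError(f"duplicate gene_ids: {dupes}")

    stop = {s.lower() for s in stoplist}
    per_doc: list[Counter[str]] = []
    total: Counter[str] = Counter()
    for d in docs:
        c = Counter(t for t in tokenize(d.text) if t not in stop)
        per_doc.append(c)
        total.update(c)

    kept = sorted(t for t, f in total.items() if f >= min_global)
    if not kept:
        raise InvalidCollectionError(
            "no term survives the stoplist and minimum-frequency filters"
        )
    index = {t: i for i, t in enumerate(kept)}

    rows, cols, vals = [], [], []
    for j, c in enumerate(per_doc):
        survivors = 0
        for t, f in c.items():
            i = index.get(t)
            if i is None:
                continue
            rows.append(i)
            cols.append(j)
            vals.append(f)
            survivors += 1
        if survivors == 0:
            raise InvalidCollectionError(
                f"document {docs[j].gene_id!r} retains no terms after filtering"
            )

    counts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(kept), len(docs)), dtype=np.int64
    )
    global_freq = np.asarray(counts.sum(axis=1)).ravel()
    doc_freq = np.asarray((counts > 0).sum(axis=1)).ravel()
    vocab = Vocabulary(kept, global_freq, doc_freq)
    return CountMatrix(counts, vocab, list(ids))


def rank_sentences(
    doc: GeneDocument, terms: Iterable[str]
) -> list[tuple[str, int]]:
    """Rank the document's sentences by total frequency of the given terms.

    Sentences are scored by the number of occurrences of any term in
    *terms* (after tokenization), sorted by score descending with ties
    kept in document order; zero-score sentences are dropped.
    """
    term_set = set(terms)
    if not term_set:
        raise ValueError("terms must be non-empty")
    scored = []
    for pos, s in enumerate(doc.sentences):
        score = sum(1 for tok in tokenize(s) if tok in term_set)
        if score > 0:
            scored.append((pos, s, score))
    scored.sort(key=lambda x: (-x[2], x[0]))
    return [(s, score) for _, s, score in scored]


def read_stoplist(path: str | Path) -> set[str]:
    """Read a stoplist file: one term per line, blank lines ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return {ln.strip().lower() for ln in lines if ln.strip()}


def _read_labels(path: Path) -> dict[str, tuple[frozenset[str], str]]:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"gene_id", "class"}
    if not required.issubset(df.columns):
        raise IOError(f"labels file {path} must have columns gene_id,class")
    out: dict[str, tuple[set[str], str]] = {}
    for _, row in df.iterrows():
        gid = row["gene_id"]
        classes, expr = out.setdefault(gid, (set(), "none"))
        if row["class"]:
            classes.add(row["class"])
        if "expression" in df.columns and row["expression"]:
            out[gid] = (classes, row["expression"])
    return {g: (frozenset(c), e) for g, (c, e) in out.items()}


def read_collection(
    path: str | Path, labels: str | Path | None = None
) -> list[GeneDocument]:
    """Read a directory of one ``.txt`` file per gene (filename = gene_id).

    An optional CSV with header ``gene_id,class[,expression]`` attaches
    class labels and expression direction; genes may appear on several
    rows to carry several classes.
    """
    path = Path(path)
    files = sorted(path.glob("*.txt"))
    if not files:
        raise InvalidCollectionError(f"no .txt documents found in {path}")
    label_map = _read_labels(Path(labels)) if labels is not None else {}
    docs = []
    for f in files:
        text = f.read_text(encoding="utf-8")
        if not text.strip():
            raise InvalidCollectionError(f"document file {f} is empty")
        classes, expr = label_map.get(f.stem, (None, "none"))
        docs.append(
            GeneDocument(gene_id=f.stem, text=text, classes=classes, expression=expr)
        )
    return docs


def gene_class_map(docs: Sequence[GeneDocument]) -> dict[str, str]:
    """Single-class map gene_id -> class for annotation/evaluation.

    Genes carrying several classes contribute their lexicographically
    first label; unlabeled genes are omitted.
    """
    out = {}
    for d in docs:
        if d.classes:
            out[d.gene_id] = min(d.classes)
    return out
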