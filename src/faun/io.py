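"""Matrix Market persistence for count and weighted matrices.

A matrix is stored under a *prefix* as three (or four) files:

``PREFIX.mtx``
    the sparse matrix in Matrix Market coordinate format;
``PREFIX.terms.txt``
    one dictionary term per line, in row order;
``PREFIX.docs.txt``
    one gene id per line, in column order;
``PREFIX.entropy.csv``
    per-term entropy weights (weighted matrices only).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.io import mmread, mmwrite

from .corpus import CountMatrix, Vocabulary
from .weighting import WeightedMatrix

__all__ = ["write_matrix", "read_count_matrix", "read_weighted_matrix"]


def _write_common(prefix: Path, matrix, terms, doc_ids) -> None:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix) + ".mtx", sparse.coo_matrix(matrix))
    Path(str(prefix) + ".terms.txt").write_text(
        "\n".join(terms) + "\n", encoding="utf-8"
    )
    Path(str(prefix) + ".docs.txt").write_text(
        "\n".join(doc_ids) + "\n", encoding="utf-8"
    )


def write_matrix(matrix: CountMatrix | WeightedMatrix, prefix: str | Path) -> None:
    """Write a matrix with its dictionary and doc-id files under *prefix*."""
    prefix = Path(prefix)
    if isinstance(matrix, CountMatrix):
        _write_common(prefix, matrix.counts, matrix.vocabulary.terms, matrix.doc_ids)
        np.savetxt(
            str(prefix) + ".freq.csv",
            np.column_stack([matrix.vocabulary.global_freq, matrix.vocabulary.doc_freq]),
            fmt="%d", delimiter=",", header="global_freq,doc_freq", comments="",
        )
    elif isinstance(matrix, WeightedMatrix):
        _write_common(prefix, matrix.A, matrix.vocabulary.terms, matrix.doc_ids)
        np.savetxt(
            str(prefix) + ".freq.csv",
            np.column_stack([matrix.vocabulary.global_freq, matrix.vocabulary.doc_freq]),
            fmt="%d", delimiter=",", header="global_freq,doc_freq", comments="",
        )
        np.savetxt(
            str(prefix) + ".entropy.csv", matrix.global_weights,
            delimiter=",", header="entropy_weight", comments="",
        )
    else:
        raise TypeError(f"cannot write {type(matrix).__name__}")


def _read_common(prefix: Path):
    mtx_path = Path(str(prefix) + ".mtx")
    if not mtx_path.exists():
        raise IOError(f"missing matrix file {mtx_path}")
    M = sparse.csr_matrix(mmread(mtx_path))
    terms = Path(str(prefix) + ".terms.txt").read_text(encoding="utf-8").splitlines()
    doc_ids = Path(str(prefix) + ".docs.txt").read_text(encoding="utf-8").splitlines()
    if M.shape[0] != len(terms):
        raise IOError(
            f"dimension mismatch: matrix has {M.shape[0]} rows "
            f"but dictionary lists {len(terms)} terms"
        )
    if M.shape[1] != len(doc_ids):
        raise IOError(
            f"dimension mismatch: matrix has {M.shape[1]} columns "
            f"but doc-id file lists {len(doc_ids)} documents"
        )
    freqs = np.loadtxt(
        str(prefix) + ".freq.csv", delimiter=",", skiprows=1, ndmin=2
    )
    vocab = Vocabulary(terms, freqs[:, 0].astype(int), freqs[:, 1].astype(int))
    return M, vocab, doc_ids


def read_count_matrix(prefix: str | Path) -> CountMatrix:
    M, vocab, doc_ids = _read_common(Path(prefix))
    return CountMatrix(M.astype(np.int64), vocab, doc_ids)


def read_weighted_matrix(prefix: str | Path) -> WeightedMatrix:
    prefix = Path(prefix)
    M, vocab, doc_ids = _read_common(prefix)
    gpath = Path(str(prefix) + ".entropy.csv")
    if not gpath.exists():
        raise IOError(f"missing entropy weight file {gpath}")
    g = np.loadtxt(gpath, delimiter=",", skiprows=1, ndmin=1)
    return WeightedMatrix(M.astype(float), g, vocab, doc_ids)
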