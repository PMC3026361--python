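"""Log-entropy term weighting: A = [w_ij] with w_ij = l_ij × g_i.

The local component l_ij = log2(1 + f_ij) damps raw frequencies; the
global component g_i = 1 + Σ_j p_ij log2(p_ij) / log2(n), with
p_ij = f_ij / Σ_j f_ij, is one minus the normalized Shannon entropy of
the term's distribution over documents. A term spread uniformly over all
documents gets g = 0 (no discriminating power); a term confined to a
single document gets g = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import CountMatrix, Vocabulary

__all__ = [
    "WeightedMatrix",
    "LogEntropyTransformer",
    "local_log_weight",
    "global_entropy_weight",
    "apply_log_entropy",
]


def local_log_weight(f):
    """Local weight l = log2(1 + f) of a nonnegative integer frequency."""
    arr = np.asarray(f)
    if np.any(arr < 0):
        raise ValueError("frequencies must be nonnegative")
    out = np.log2(1.0 + arr)
    return float(out) if np.isscalar(f) else out


def global_entropy_weight(row_counts: Sequence[float], n: int | None = None) -> float:
    """Entropy weight g ∈ [0, 1] of one term from its per-document counts.

    ``n`` defaults to ``len(row_counts)``; it must be >= 2 since the
    normalization divides by log2(n). The convention 0·log(0) = 0 applies.
    """
    counts = np.asarray(row_counts, dtype=float)
    if n is None:
        n = counts.size
    if n < 2:
        raise ValueError("entropy weighting needs n >= 2 documents")
    total = counts.sum()
    if total <= 0:
        raise ValueError("term must occur in at least one document")
    p = counts[counts > 0] / total
    return float(1.0 + np.sum(p * np.log2(p)) / np.log2(n))


def _entropy_weights_sparse(counts: sparse.spmatrix, n_docs: int) -> np.ndarray:
    """Vectorized g_i for all rows of a terms×docs sparse count matrix."""
    A = sparse.csr_matrix(counts, dtype=float)
    row_tot = np.asarray(A.sum(axis=1)).ravel()
    g = np.zeros(A.shape[0])
    nz = row_tot > 0
    # p log2 p summed per row, using the CSR data array directly
    p = A.data / np.repeat(row_tot, np.diff(A.indptr))
    contrib = p * np.log2(p, where=p > 0, out=np.zeros_like(p))
    row_entropy = np.add.reduceat(
        contrib, A.indptr[:-1], dtype=float
    ) if A.nnz else np.zeros(A.shape[0])
    # reduceat misbehaves on empty rows: recompute those as 0
    empty = np.diff(A.indptr) == 0
    row_entropy[empty] = 0.0
    g[nz] = 1.0 + row_entropy[nz] / np.log2(n_docs)
    # clip tiny negative rounding artifacts
    return np.clip(g, 0.0, 1.0)


class LogEntropyTransformer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer applying log-entropy weighting.

    Follows the sklearn orientation: ``X`` has shape (n_documents,
    n_terms), e.g. the output of a count vectorizer. ``fit`` learns the
    per-term entropy weights ``entropy_weights_`` from the collection;
    ``transform`` returns log2(1 + f) scaled column-wise by them, with
    the sparsity pattern of ``X`` preserved.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] < 2:
            raise ValueError("entropy weighting needs >= 2 documents")
        self.n_documents_ = X.shape[0]
        self.entropy_weights_ = _entropy_weights_sparse(X.T, X.shape[0])
        return self

    def transform(self, X):
        check_is_fitted(self, "entropy_weights_")
        X = self._validate(X)
        if X.shape[1] != self.entropy_weights_.size:
            raise ValueError("X has a different number of terms than fit data")
        W = X.copy().astype(float)
        W.data = np.log2(1.0 + W.data)
        return W.multiply(sparse.csr_matrix(self.entropy_weights_)).tocsr()

    @staticmethod
    def _validate(X) -> sparse.csr_matrix:
        X = sparse.csr_matrix(X)
        if X.nnz and X.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        return X


@dataclass
class WeightedMatrix:
    """Sparse m×n log-entropy weighted term-by-document matrix."""

    A: sparse.csr_matrix
    global_weights: np.ndarray
    vocabulary: Vocabulary
    doc_ids: list[str]

    def __post_init__(self) -> None:
        self.A = sparse.csr_matrix(self.A)
        self.global_weights = np.asarray(self.global_weights, dtype=float)
        m, n = self.A.shape
        if m != len(self.vocabulary) or m != self.global_weights.size:
            raise ValueError("matrix rows, vocabulary and weights must align")
        if n != len(self.doc_ids):
            raise ValueError("matrix columns and doc_ids must align")
        if self.global_weights.size and (
            self.global_weights.min() < 0 or self.global_weights.max() > 1
        ):
            raise ValueError("entropy weights must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape


def apply_log_entropy(counts: CountMatrix) -> WeightedMatrix:
    """Weight a count matrix: w_ij = log2(1 + f_ij) × g_i.

    Uniform terms end up as all-zero rows; they are kept so the
    dictionary row indices stay stable.
    """
    tr = LogEntropyTransformer().fit(counts.counts.T)
    A = tr.transform(counts.counts.T).T.tocsr()
    # drop explicitly-stored zeros created where g_i = 0
    A.eliminate_zeros()
    return WeightedMatrix(A, tr.entropy_weights_, counts.vocabulary, list(counts.doc_ids))
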