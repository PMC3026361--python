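"""Interpreting a fitted model: top terms, gene filters, gene correlation.

Each column of W is a *feature* — a term-usage pattern readable as a
biological concept once its dominant terms are inspected. Each row of H
gives every gene document's association strength with one feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .nmf import NMFModel

__all__ = [
    "FeatureAnnotation",
    "CorrelationResult",
    "top_terms",
    "genes_for_feature",
    "feature_window",
    "gene_correlation",
]

AssignmentMode = Literal["global_threshold", "local_percentile", "relative_max"]

#: paper-default parameters for the three gene-filter modes
DEFAULT_GLOBAL_THRESHOLD = 1.0
DEFAULT_LOCAL_PERCENTILE = 70.0
DEFAULT_RELATIVE_MAX = 1.0


@dataclass
class FeatureAnnotation:
    feature_index: int
    label: str
    source: Literal["manual", "automatic"]

    def __post_init__(self) -> None:
        if self.feature_index < 0:
            raise ValueError("feature_index must be nonnegative")
        if self.source not in ("manual", "automatic"):
            raise ValueError(f"invalid annotation source {self.source!r}")


def _check_feature(model: NMFModel, feature: int) -> None:
    if not 0 <= feature < model.rank:
        raise IndexError(f"feature {feature} out of range for rank {model.rank}")


def top_terms(
    model: NMFModel,
    feature: int,
    limit: int = 12,
    entropy_min: float = 0.0,
) -> list[tuple[str, float]]:
    """Dominant terms of one feature, entropy-filtered.

    Terms with entropy weight g_i >= ``entropy_min`` are sorted by their
    W weight in the feature (descending, ties broken lexicographically)
    and truncated to ``limit``. Low-entropy terms are used consistently
    across the whole collection and are poor concept discriminators, so
    raising ``entropy_min`` focuses the listing.
    """
    _check_feature(model, feature)
    if model.vocabulary is None:
        raise ValueError("model carries no vocabulary")
    g = model.global_weights
    if g is None:
        g = np.ones(len(model.vocabulary))
    col = model.W[:, feature]
    order = sorted(
        (i for i in range(len(col)) if g[i] >= entropy_min),
        key=lambda i: (-col[i], model.vocabulary.terms[i]),
    )
    return [(model.vocabulary.terms[i], float(col[i])) for i in order[:limit]]


def genes_for_feature(
    model: NMFModel,
    feature: int,
    mode: AssignmentMode = "global_threshold",
    parameter: float | None = None,
) -> list[tuple[str, float]]:
    """Genes associated with a feature under one of three filters.

    ``global_threshold(t)``
        keep genes with H[feature, gene] >= t (default t = 1.0, the
        medium global setting).
    ``local_percentile(p)``
        keep a gene iff its weight on this feature reaches the p-th
        nearest-rank percentile of that gene's own k feature weights
        (default p = 70).
    ``relative_max(f_tau)``
        keep genes within a fraction f_tau of the feature's maximum
        weight: H[feature, gene] >= max_g H[feature, g] × f_tau.

    All modes only ever return genes with strictly positive weight.
    Results are sorted by weight descending (strength of association),
    ties by gene order.
    """
    _check_feature(model, feature)
    row = model.H[feature, :]
    n = row.size
    doc_ids = model.doc_ids if model.doc_ids is not None else [str(j) for j in range(n)]

    if mode == "global_threshold":
        t = DEFAULT_GLOBAL_THRESHOLD if parameter is None else parameter
        keep = row >= t
    elif mode == "local_percentile":
        p = DEFAULT_LOCAL_PERCENTILE if parameter is None else parameter
        if not 0 <= p <= 100:
            raise ValueError("percentile must be in [0, 100]")
        k = model.rank
        # nearest-rank percentile over the gene's own k feature weights
        rank_idx = max(int(math.ceil(p / 100.0 * k)), 1) - 1
        thresholds = np.sort(model.H, axis=0)[rank_idx, :]
        keep = row >= thresholds
    elif mode == "relative_max":
        f_tau = DEFAULT_RELATIVE_MAX if parameter is None else parameter
        if not 0 <= f_tau <= 1:
            raise ValueError("f_tau must be in [0, 1]")
        keep = row >= row.max() * f_tau
    else:
        raise ValueError(f"unknown mode {mode!r}")

    keep &= row > 0
    idx = np.flatnonzero(keep)
    order = idx[np.lexsort((idx, -row[idx]))]
    return [(doc_ids[j], float(row[j])) for j in order]


def feature_window(feature: int, rank: int) -> tuple[int, int, int]:
    """The feature plus its left and right neighbors, clamped inward.

    At the boundaries the 3-window shifts inward rather than wrapping,
    so the correlated features stay adjacent resolutions of each other.
    """
    if rank < 3:
        raise ValueError("a correlation window needs rank >= 3")
    if not 0 <= feature < rank:
        raise IndexError(f"feature {feature} out of range for rank {rank}")
    lo = min(max(feature - 1, 0), rank - 3)
    return (lo, lo + 1, lo + 2)


@dataclass
class CorrelationResult:
    """Pearson gene–gene correlation over a selected feature subset.

    ``R[i, j]`` is the correlation of gene i's and gene j's H-value
    vectors restricted to ``features_used``; cells where either vector
    has zero variance are NaN and flagged in ``undefined``. ``strengths``
    keeps the underlying H values (genes × features) so the feature
    contributions driving any correlation can be inspected.
    """

    features_used: tuple[int, ...]
    genes: list[str]
    R: np.ndarray
    undefined: np.ndarray
    strengths: np.ndarray

    def pair_breakdown(self, i: int, j: int) -> dict[int, tuple[float, float]]:
        """Per-feature H contributions for one gene pair."""
        return {
            f: (float(self.strengths[i, a]), float(self.strengths[j, a]))
            for a, f in enumerate(self.features_used)
        }


def gene_correlation(
    model: NMFModel,
    features: Sequence[int],
    genes: Sequence[str] | None = None,
) -> CorrelationResult:
    """Pearson correlation of gene H-vectors over >= 3 selected features."""
    features = tuple(dict.fromkeys(int(f) for f in features))
    if len(features) < 3:
        raise ValueError("a minimum of 3 features must be selected")
    for f in features:
        _check_feature(model, f)
    doc_ids = model.doc_ids if model.doc_ids is not None else [
        str(j) for j in range(model.H.shape[1])
    ]
    if genes is None:
        gene_idx = list(range(len(doc_ids)))
    else:
        pos = {g: j for j, g in enumerate(doc_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"unknown genes: {missing}")
        gene_idx = [pos[g] for g in genes]
    if not gene_idx:
        raise ValueError("genes must be nonempty")

    V = model.H[np.ix_(list(features), gene_idx)].T.astype(float)  # genes × features
    centered = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    defined = norms > 0
    safe = np.where(defined, norms, 1.0)
    unit = centered / safe[:, None]
    R = unit @ unit.T
    np.clip(R, -1.0, 1.0, out=R)
    undefined = ~(defined[:, None] & defined[None, :])
    R[undefined] = np.nan
    np.fill_diagonal(R, np.where(defined, 1.0, np.nan))
    return CorrelationResult(
        features_used=features,
        genes=[doc_ids[j] for j in gene_idx],
        R=R,
        undefined=undefined,
        strengths=V,
    )
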