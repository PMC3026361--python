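"""Feature annotation, gene classification and evaluation.

Features are mapped to known gene classes (automatically, from labeled
genes passing the relative-max filter), genes are then classified either
by their strongest annotated feature or multi-label by every feature
they pass, and outcomes are scored with the 1/(number of assigned
classes) correctness rule plus per-class precision/recall/F1.

New documents can be classified against a fitted model without
refitting: each feature is scored by the log-entropy weight of the
document's surviving terms times the feature's W column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import Vocabulary, tokenize
from .nmf import NMFModel, fit_nmf

__all__ = [
    "UNASSIGNED",
    "UNCLASSIFIABLE",
    "ClassMap",
    "EvalReport",
    "NewDocumentScores",
    "auto_annotate",
    "classify_strongest",
    "multilabel_assign",
    "correctness",
    "total_correctness",
    "precision_recall_f1",
    "classify_new_document",
    "evaluate",
    "FaunClassifier",
]

#: sentinel class for features where no gene passes the filter
UNASSIGNED = "unassigned"
#: sentinel outcome for genes with an all-zero H column
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class ClassMap:
    """Per-feature class labels with their provenance."""

    labels: dict[int, str]
    provenance: Literal["automatic", "manual"]
    f_tau: float | None = None

    def __getitem__(self, feature: int) -> str:
        return self.labels[feature]

    def classes(self) -> set[str]:
        return {c for c in self.labels.values() if c != UNASSIGNED}


def _passing(row: np.ndarray, f_tau: float) -> np.ndarray:
    """Indices passing the relative-max filter H >= max H × f_tau."""
    keep = (row >= row.max() * f_tau) & (row > 0)
    return np.flatnonzero(keep)


def auto_annotate(
    model: NMFModel,
    gene_classes: Mapping[str, str],
    f_tau: float = 1.0,
) -> ClassMap:
    """Label every feature with the class best supported by its genes.

    For each feature, the genes passing the relative-max filter
    (H >= max H × f_tau) vote with their H weights; the class with the
    largest summed weight wins. Ties go to the class of the single
    highest-weight gene, then lexicographic. A feature with no passing
    genes gets the ``unassigned`` sentinel.

    At f_tau = 1 only the argmax gene passes, so each feature is simply
    labeled by its strongest gene's class.
    """
    if not 0 <= f_tau <= 1:
        raise ValueError("f_tau must be in [0, 1]")
    doc_ids = model.doc_ids or [str(j) for j in range(model.H.shape[1])]
    labels: dict[int, str] = {}
    for f in range(model.rank):
        row = model.H[f, :]
        idx = _passing(row, f_tau)
        if idx.size == 0:
            labels[f] = UNASSIGNED
            continue
        unlabeled = [doc_ids[j] for j in idx if doc_ids[j] not in gene_classes]
        if unlabeled:
            raise KeyError(f"genes without class labels: {sorted(set(unlabeled))}")
        weight: Counter[str] = Counter()
        for j in idx:
            weight[gene_classes[doc_ids[j]]] += row[j]
        best = max(weight.values())
        tied = sorted(c for c, w in weight.items() if w == best)
        if len(tied) == 1:
            labels[f] = tied[0]
        else:
            # tie: the single highest-weight gene decides, then lexicographic
            order = sorted(idx, key=lambda j: (-row[j], doc_ids[j]))
            top_class = next(
                (gene_classes[doc_ids[j]] for j in order
                 if gene_classes[doc_ids[j]] in tied),
                tied[0],
            )
            labels[f] = top_class
    return ClassMap(labels=labels, provenance="automatic", f_tau=f_tau)


def _gene_column(model: NMFModel, gene: int | str) -> int:
    if isinstance(gene, str):
        doc_ids = model.doc_ids or []
        try:
            return doc_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None
    return int(gene)


def classify_strongest(model: NMFModel, class_map: ClassMap, gene: int | str) -> str:
    """Class of the gene's strongest feature (largest H column entry).

    Ties resolve to the lowest feature index; a gene whose H column is
    all zero is ``unclassifiable`` (counted wrong in accuracy).
    """
    j = _gene_column(model, gene)
    col = model.H[:, j]
    if col.max() <= 0:
        return UNCLASSIFIABLE
    return class_map[int(np.argmax(col))]


def multilabel_assign(
    model: NMFModel, class_map: ClassMap, f_tau: float = 1.0
) -> dict[str, frozenset[str]]:
    """Per-gene class sets from every feature whose filter the gene passes.

    A gene's set is the union of the labels of all features where
    H[f, gene] >= max_g H[f, g] × f_tau; features left ``unassigned``
    contribute nothing. Sets may be empty (correctness 0).
    """
    if not 0 <= f_tau <= 1:
        raise ValueError("f_tau must be in [0, 1]")
    doc_ids = model.doc_ids or [str(j) for j in range(model.H.shape[1])]
    assigned: dict[str, set[str]] = {g: set() for g in doc_ids}
    for f in range(model.rank):
        label = class_map[f]
        if label == UNASSIGNED:
            continue
        for j in _passing(model.H[f, :], f_tau):
            assigned[doc_ids[j]].add(label)
    return {g: frozenset(s) for g, s in assigned.items()}


def correctness(assigned: Iterable[str], truth: str) -> float:
    """1/(number of assigned classes) if the truth is among them, else 0."""
    assigned = set(assigned)
    if not assigned or truth not in assigned:
        return 0.0
    return 1.0 / len(assigned)


def total_correctness(outcomes: Sequence[float]) -> float:
    """Mean correctness over genes, as a percentage in [0, 100]."""
    if len(outcomes) == 0:
        raise ValueError("total correctness of an empty collection is undefined")
    return 100.0 * float(np.mean(outcomes))


def precision_recall_f1(
    predicted: Iterable[str], truth: Iterable[str]
) -> tuple[float, float, float]:
    """Set precision, recall and F1 (harmonic mean) of a predicted gene set.

    An empty predicted set yields precision 0 by convention; an empty
    truth set is an error.
    """
    predicted, truth = set(predicted), set(truth)
    if not truth:
        raise ValueError("truth set must be nonempty")
    hit = len(predicted & truth)
    p = hit / len(predicted) if predicted else 0.0
    r = hit / len(truth)
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


@dataclass
class NewDocumentScores:
    """Ranked feature scores for a new document against a fitted model."""

    ranking: list[tuple[int, float]]
    kept_terms: dict[str, int]
    no_signal: bool  # True when no term survived the filters

    @property
    def top_feature(self) -> int | None:
        return None if self.no_signal else self.ranking[0][0]


def classify_new_document(
    text: str,
    W: np.ndarray,
    vocabulary: Vocabulary,
    global_weights: np.ndarray,
    entropy_threshold: float = 0.0,
    freq_threshold: int = 0,
    stoplist: Iterable[str] = (),
) -> NewDocumentScores:
    """Score a new document against each feature of a fitted model.

    The document is tokenized; stop words, out-of-vocabulary terms,
    terms with entropy weight g <= ``entropy_threshold`` and terms with
    in-document frequency f <= ``freq_threshold`` are dropped (both
    comparisons strict). Each feature's score is

        Σ_kept terms  log2(1 + f_term) · g_term · W[term, feature],

    i.e. the model's own log-entropy weighting applied to the new
    document, projected onto the feature. Features come back sorted by
    score descending (ties by index); no refit of the model is needed.
    """
    stop = {s.lower() for s in stoplist}
    index = vocabulary.index()
    freqs = Counter(t for t in tokenize(text) if t not in stop and t in index)
    kept = {
        t: f
        for t, f in freqs.items()
        if f > freq_threshold and global_weights[index[t]] > entropy_threshold
    }
    scores = np.zeros(W.shape[1])
    for t, f in kept.items():
        i = index[t]
        scores += np.log2(1.0 + f) * global_weights[i] * W[i, :]
    order = sorted(range(W.shape[1]), key=lambda f: (-scores[f], f))
    ranking = [(f, float(scores[f])) for f in order]
    return NewDocumentScores(
        ranking=ranking, kept_terms=kept, no_signal=not kept or scores.max() <= 0
    )


@dataclass
class EvalReport:
    """Classification quality of a fitted, annotated model."""

    accuracy_strongest: float  # percent of genes with correct strongest feature
    total_correctness: float  # percent, multi-label 1/j scoring
    per_class: dict[str, tuple[float, float, float]]  # class -> (p, r, f1)
    n_genes: int


def evaluate(
    model: NMFModel,
    class_map: ClassMap,
    gene_classes: Mapping[str, str],
    f_tau: float = 1.0,
) -> EvalReport:
    """Accuracy, total correctness and per-class precision/recall/F1."""
    doc_ids = model.doc_ids or [str(j) for j in range(model.H.shape[1])]
    missing = [g for g in doc_ids if g not in gene_classes]
    if missing:
        raise KeyError(f"genes without class labels: {missing}")

    hits = [
        classify_strongest(model, class_map, g) == gene_classes[g] for g in doc_ids
    ]
    accuracy = 100.0 * float(np.mean(hits))

    assigned = multilabel_assign(model, class_map, f_tau)
    scores = [correctness(assigned[g], gene_classes[g]) for g in doc_ids]
    tc = total_correctness(scores)

    per_class = {}
    for c in sorted(set(gene_classes[g] for g in doc_ids)):
        predicted = {g for g in doc_ids if c in assigned[g]}
        truth = {g for g in doc_ids if gene_classes[g] == c}
        per_class[c] = precision_recall_f1(predicted, truth)
    return EvalReport(
        accuracy_strongest=accuracy,
        total_correctness=tc,
        per_class=per_class,
        n_genes=len(doc_ids),
    )


class FaunClassifier(ClassifierMixin, BaseEstimator):
    """Strongest-feature gene classifier as a scikit-learn estimator.

    ``fit(X, y)`` takes log-entropy weighted documents as rows of ``X``
    (n_documents × n_terms, e.g. the output of
    :class:`~faun.weighting.LogEntropyTransformer`) and their class
    labels ``y``; it factorizes Xᵀ ≈ WH and auto-annotates every feature
    from the labels. ``predict(X)`` scores new weighted documents by
    projection onto W and returns the label of the top feature, so it
    composes with sklearn pipelines and model selection.
    """

    def __init__(
        self,
        n_components: int = 10,
        *,
        f_tau: float = 1.0,
        init: str = "nndsvd_mean_fill",
        max_iter: int = 1000,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.f_tau = f_tau
        self.init = init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = sparse.csr_matrix(X)
        y = np.asarray(y)
        if X.shape[0] != y.size:
            raise ValueError("X rows and y length differ")
        model = fit_nmf(
            X.T.tocsr(),
            self.n_components,
            init=self.init,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        gene_classes = {str(j): str(y[j]) for j in range(y.size)}
        self.model_ = model
        self.class_map_ = auto_annotate(model, gene_classes, f_tau=self.f_tau)
        self.feature_labels_ = np.array(
            [self.class_map_.labels[f] for f in range(model.rank)], dtype=object
        )
        self.classes_ = np.unique(y.astype(str))
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return np.asarray(sparse.csr_matrix(X) @ self.model_.W)

    def predict(self, X):
        scores = self.decision_function(X)
        top = np.argmax(scores, axis=1)
        labels = self.feature_labels_[top]
        labels[scores.max(axis=1) <= 0] = UNCLASSIFIABLE
        return labels
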