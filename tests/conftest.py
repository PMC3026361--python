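import numpy as np
import pytest
from scipy import sparse

from faun import (
    GeneDocument,
    TopicSpec,
    apply_log_entropy,
    auto_annotate,
    build_count_matrix,
    fit_nmf,
    generate_corpus,
)


@pytest.fixture(scope="session")
def tiny_docs():
    """Four documents, two obvious topics (DNA repair vs insulin)."""
    return [
        GeneDocument("atm", "atm repair damage. atm repair dna. dna damage checkpoint."),
        GeneDocument("brca1", "brca1 repair dna. damage repair brca1. dna checkpoint."),
        GeneDocument("ins", "insulin receptor signaling. insulin glucose. receptor signaling glucose."),
        GeneDocument("igf1", "igf1 insulin receptor. glucose signaling. insulin receptor igf1."),
    ]


@pytest.fixture(scope="session")
def tiny_counts(tiny_docs):
    return build_count_matrix(tiny_docs, stoplist=set(), min_global=2)


@pytest.fixture(scope="session")
def tiny_weighted(tiny_counts):
    return apply_log_entropy(tiny_counts)


@pytest.fixture(scope="session")
def synth_spec():
    """The study corpus shape: 5 topics, 110 documents in uneven categories."""
    return TopicSpec(docs_per_topic=(26, 10, 25, 37, 12), seed=11)


@pytest.fixture(scope="session")
def synth_model(synth_spec):
    """Fitted k=5 model of the synthetic corpus plus its labels."""
    docs, truth = generate_corpus(synth_spec)
    counts = build_count_matrix(docs)
    weighted = apply_log_entropy(counts)
    model = fit_nmf(weighted, 5)
    gene_classes = {d.gene_id: min(d.classes) for d in docs}
    return model, gene_classes, docs, truth


@pytest.fixture(scope="session")
def annotated(synth_model):
    model, gene_classes, docs, truth = synth_model
    return model, auto_annotate(model, gene_classes, f_tau=1.0), gene_classes


def random_count_matrix(rng, m, n, density=0.4, max_count=8):
    """Random nonnegative integer terms×docs matrix with no zero rows/cols."""
    M = (rng.random((m, n)) < density) * rng.integers(1, max_count + 1, (m, n))
    for i in range(m):
        if M[i].sum() == 0:
            M[i, rng.integers(n)] = rng.integers(1, max_count + 1)
    for j in range(n):
        if M[:, j].sum() == 0:
            M[rng.integers(m), j] = rng.integers(1, max_count + 1)
    return M.astype(np.int64)
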