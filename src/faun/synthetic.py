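"""Topic-structured synthetic gene-document corpora with known truth.

Stands in for hand-compiled literature collections: k* latent topics,
each with a disjoint set of signature terms, generate documents whose
tokens come from the topic signature with probability
``signature_fraction`` and from a shared background pool otherwise.
Because every document has a known generating topic, the whole pipeline
(count matrix → weighting → NMF → annotation → classification) can be
tested end to end without any download.

Defaults describe a review-derived study-scale collection: 5 topics, 110 documents of
~200 words over a few-hundred-term dictionary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import GeneDocument

__all__ = ["TopicSpec", "generate_corpus", "generate_heldout", "write_corpus"]

#: per-category document counts of a 110-gene review-derived study collection
STUDY_DOC_COUNTS = (26, 10, 25, 37, 12)


@dataclass(frozen=True)
class TopicSpec:
    """Generative settings for a synthetic corpus."""

    n_topics: int = 5
    signature_terms_per_topic: int = 30
    background_terms: int = 200
    docs_per_topic: int | tuple[int, ...] = 20
    words_per_doc: int = 200
    signature_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("need at least one topic")
        if self.signature_terms_per_topic < 1 or self.background_terms < 1:
            raise ValueError("term pool sizes must be positive")
        counts = self.doc_counts()
        if len(counts) != self.n_topics or any(c < 1 for c in counts):
            raise ValueError("docs_per_topic must be positive for every topic")
        if self.words_per_doc < 1:
            raise ValueError("words_per_doc must be positive")
        if not 0 < self.signature_fraction <= 1:
            raise ValueError("signature_fraction must be in (0, 1]")

    def doc_counts(self) -> tuple[int, ...]:
        if isinstance(self.docs_per_topic, int):
            return (self.docs_per_topic,) * self.n_topics
        return tuple(self.docs_per_topic)

    def signature_terms(self, topic: int) -> list[str]:
        return [
            f"topic{topic}sig{i:03d}"
            for i in range(self.signature_terms_per_topic)
        ]

    def background_pool(self) -> list[str]:
        return [f"background{i:04d}" for i in range(self.background_terms)]


def _compose_doc(
    spec: TopicSpec, topic: int, rng: np.random.Generator
) -> str:
    sig = spec.signature_terms(topic)
    bg = spec.background_pool()
    from_sig = rng.random(spec.words_per_doc) < spec.signature_fraction
    words = np.where(
        from_sig,
        rng.choice(sig, size=spec.words_per_doc),
        rng.choice(bg, size=spec.words_per_doc),
    )
    # sentence breaks every ~15 words so sentence ranking has something to rank
    parts = []
    for s in range(0, len(words), 15):
        parts.append(" ".join(words[s : s + 15]) + ".")
    return " ".join(parts)


def generate_corpus(
    spec: TopicSpec,
) -> tuple[list[GeneDocument], dict[str, int]]:
    """Generate a labeled corpus and its gene → topic truth map.

    Documents are named ``gene_000``, ``gene_001``, … in topic-block
    order; each carries its generating topic as class ``topic<t>``.
    Identical spec (including seed) gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    docs: list[GeneDocument] = []
    truth: dict[str, int] = {}
    gid = 0
    for topic, count in enumerate(spec.doc_counts()):
        for _ in range(count):
            gene_id = f"gene_{gid:03d}"
            docs.append(
                GeneDocument(
                    gene_id=gene_id,
                    text=_compose_doc(spec, topic, rng),
                    classes=frozenset({f"topic{topic}"}),
                )
            )
            truth[gene_id] = topic
            gid += 1
    return docs, truth


def generate_heldout(
    spec: TopicSpec, topic: int, n_docs: int
) -> list[GeneDocument]:
    """Fresh documents from one topic, for classifier testing.

    Uses a seed stream derived from (spec.seed, topic) that is disjoint
    from the training corpus stream, so held-out documents are new draws
    from the same generative process.
    """
    if not 0 <= topic < spec.n_topics:
        raise ValueError(f"topic {topic} out of range")
    rng = np.random.default_rng([spec.seed, 7919, topic])
    return [
        GeneDocument(
            gene_id=f"heldout_t{topic}_{i:03d}",
            text=_compose_doc(spec, topic, rng),
            classes=frozenset({f"topic{topic}"}),
        )
        for i in range(n_docs)
    ]


def write_corpus(
    docs: Sequence[GeneDocument],
    truth: dict[str, int],
    directory: str | Path,
) -> None:
    """Write one .txt per document plus labels.csv and truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lines = ["gene_id,class"]
    for doc in docs:
        (d / f"{doc.gene_id}.txt").write_text(doc.text, encoding="utf-8")
        for c in sorted(doc.classes or ()):
            lines.append(f"{doc.gene_id},{c}")
    (d / "labels.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    (d / "truth.json").write_text(json.dumps(truth, indent=0), encoding="utf-8")
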