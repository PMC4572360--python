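"""Supervised k-nearest-neighbour GO classifier.

The classifier assigns to an unseen abstract the GO terms that are most
prevalent among the k most lexically similar curated abstracts in a
knowledge base (k = 100 by default). Because the vote is over curated
annotations rather than the abstract's own wording, it can propose terms
that never appear literally in the input text — the property that makes
deep question answering possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Collection, Mapping

from .corpus_io import Document, KnowledgeBase
from .dict_classifier import ScoredTerm
from .ontology import Ontology, namespace_terms
from .retrieval import Index, RetrievalParams, build_index, search, tokenize

__all__ = [
    "KBIndex",
    "KnowledgeBaseError",
    "build_kb_index",
    "nearest_neighbours",
    "classify_knn",
]

logger = logging.getLogger(__name__)


class KnowledgeBaseError(Exception):
    """Raised when the knowledge base cannot support classification."""


@dataclass
class KBIndex:
    """Retrieval index over exactly the annotated documents, plus the
    annotations they vote with."""

    index: Index
    kb: KnowledgeBase
    k: int = 100

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def build_kb_index(
    kb: KnowledgeBase, corpus: Mapping[str, Document], k: int = 100
) -> KBIndex:
    """Index the knowledge-base abstracts present in the corpus.

    Annotated pmids missing from the corpus are dropped with a warning; an
    empty intersection is an error.
    """
    texts: dict[str, str] = {}
    missing = []
    for pmid in kb.annotations:
        doc = corpus.get(pmid)
        if doc is None:
            missing.append(pmid)
        else:
            texts[pmid] = doc.full_text
    if missing:
        logger.warning(
            "%d annotated pmids missing from corpus (e.g. %s)",
            len(missing),
            missing[:3],
        )
    if not texts:
        raise KnowledgeBaseError(
            "no annotated pmid has a corpus document to index"
        )
    return KBIndex(index=build_index(texts), kb=kb, k=k)


def nearest_neighbours(
    kb_index: KBIndex,
    text: str,
    k: int | None = None,
    exclude_pmids: Collection[str] = frozenset(),
) -> list[tuple[str, float]]:
    """The up-to-k knowledge-base documents with positive BM25 similarity
    to the text, after removing ``exclude_pmids``."""
    k = kb_index.k if k is None else k
    if k < 1:
        raise ValueError("k must be >= 1")
    if not tokenize(text):
        raise ValueError("text is empty after tokenization")
    excluded = set(exclude_pmids)
    eligible = set(kb_index.index.doc_lengths) - excluded
    if not eligible:
        raise KnowledgeBaseError("knowledge base is empty after exclusion")
    params = RetrievalParams(n_retrieved=kb_index.index.n_docs)
    ranked = search(kb_index.index, text, params)
    return [
        (pmid, score)
        for pmid, score in ranked
        if pmid not in excluded and score > 0.0
    ][:k]


def classify_knn(
    kb_index: KBIndex,
    text: str,
    k: int | None = None,
    m: int = 5,
    exclude_pmids: Collection[str] = frozenset(),
    *,
    namespace: str | None = None,
    ontology: Ontology | None = None,
    weight_by_similarity: bool = False,
) -> list[ScoredTerm]:
    """Top-m GO terms voted by the k nearest curated abstracts.

    Neighbours are the (up to) k knowledge-base documents with positive
    BM25 similarity to the text, after removing ``exclude_pmids`` (the
    leave-out protocol). A term's score is the number of neighbours
    annotated with it ("most prevalent" voting); ties break by summed
    neighbour similarity, then GO id. ``weight_by_similarity`` switches the
    vote weight from 1 to the neighbour's BM25 score; it is off by default.

    When ``namespace`` is given (with an ontology), candidate terms are
    restricted to that namespace before the top-m cutoff, so off-axis terms
    never consume answer slots.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    neighbours = nearest_neighbours(kb_index, text, k, exclude_pmids)

    allowed: set[str] | None = None
    if namespace is not None:
        if ontology is None:
            raise ValueError("namespace filtering requires an ontology")
        allowed = namespace_terms(ontology, namespace)

    votes: dict[str, float] = {}
    similarity: dict[str, float] = {}
    for pmid, score in neighbours:
        for go_id in kb_index.kb.annotations.get(pmid, ()):
            if allowed is not None and go_id not in allowed:
                continue
            votes[go_id] = votes.get(go_id, 0.0) + (
                score if weight_by_similarity else 1.0
            )
            similarity[go_id] = similarity.get(go_id, 0.0) + score
    ordered = sorted(
        votes,
        key=lambda g: (-votes[g], -similarity[g], g),
    )
    return [ScoredTerm(go_id=g, score=votes[g]) for g in ordered[:m]]
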