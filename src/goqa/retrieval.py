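"""Tokenization, inverted index and Okapi BM25 ranked retrieval.

Two document-ordering modes are provided, mirroring the two search engines a
literature QA system can sit on: ``bm25`` (vector-space relevance ranking)
and ``boolean_recency`` (documents containing every query token, newest
first — a local stand-in for PubMed's reverse-time Boolean search). A
remote-PubMed backend would slot in behind the same ``search`` signature; it
is deliberately not implemented here.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

from .ontology import normalize

__all__ = [
    "DEFAULT_STOPWORDS",
    "RetrievalParams",
    "Index",
    "RetrievalError",
    "tokenize",
    "build_index",
    "search",
    "bm25_idf",
    "bm25_term_score",
]

# Small English stoplist covering function words common in questions and
# abstracts. Applied identically to indexed text and queries.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be been but by for from has have in is it its of on
    or that the this to was were which with what how why when where who whose
    does do did can could should would will not no nor also than then there
    these those between into through during before after above below under
    over such other some any each both more most""".split()
)



class RetrievalError(Exception):
    """Raised on invalid retrieval requests (empty query, missing dates...)."""


def _light_stem(token: str) -> str:
    """Minimal plural stripper: -ies -> -y, else trailing -s (not -ss)."""
    if len(token) <= 3:
        return token
    if token.endswith("ies"):
        return token[:-3] + "y"
    if token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


def tokenize(
    text: str,
    *,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    stem: bool = False,
) -> list[str]:
    """Normalized word tokens with stopwords removed.

    Stemming (a light plural stripper) is off by default.
    """
    tokens = [t for t in normalize(text).split() if t not in stopwords]
    if stem:
        tokens = [_light_stem(t) for t in tokens]
    return tokens


@dataclass
class RetrievalParams:
    """BM25 and retrieval-depth parameters.

    k1 and b are the conventional Okapi/Terrier defaults; n_retrieved is the
    number of abstracts handed to answer extraction (100 in the QA setting).
    """

    k1: float = 1.2
    b: float = 0.75
    n_retrieved: int = 100
    mode: str = "bm25"

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError("k1 must be > 0")
        if not 0 <= self.b <= 1:
            raise ValueError("b must be in [0, 1]")
        if self.n_retrieved < 1:
            raise ValueError("n_retrieved must be >= 1")
        if self.mode not in ("bm25", "boolean_recency"):
            raise ValueError(f"unknown retrieval mode {self.mode!r}")


@dataclass
class Index:
    postings: dict[str, list[tuple[str, int]]]
    doc_lengths: dict[str, int]
    avg_doc_length: float
    n_docs: int
    dates: dict[str, date] = field(default_factory=dict)
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    stem: bool = False

    def doc_frequency(self, token: str) -> int:
        return len(self.postings.get(token, ()))


def build_index(
    texts: Mapping[str, str] | Iterable[tuple[str, str]],
    *,
    dates: Mapping[str, date] | None = None,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    stem: bool = False,
) -> Index:
    """Build an inverted index over ``doc id -> text``.

    Deterministic given input order; posting lists are kept sorted by doc id.
    """
    items = list(texts.items()) if isinstance(texts, Mapping) else list(texts)
    if not items:
        raise RetrievalError("cannot index an empty corpus")
    postings: dict[str, dict[str, int]] = {}
    doc_lengths: dict[str, int] = {}
    for doc_id, text in items:
        tokens = tokenize(text, stopwords=stopwords, stem=stem)
        doc_lengths[doc_id] = len(tokens)
        for token in tokens:
            bucket = postings.setdefault(token, {})
            bucket[doc_id] = bucket.get(doc_id, 0) + 1
    n_docs = len(doc_lengths)
    avg = sum(doc_lengths.values()) / n_docs
    sorted_postings = {
        token: sorted(bucket.items()) for token, bucket in postings.items()
    }
    return Index(
        postings=sorted_postings,
        doc_lengths=doc_lengths,
        avg_doc_length=avg,
        n_docs=n_docs,
        dates=dict(dates) if dates else {},
        stopwords=stopwords,
        stem=stem,
    )


def bm25_idf(n_docs: int, doc_frequency: int) -> float:
    """Non-negative idf: ln(1 + (N - df + 0.5) / (df + 0.5))."""
    return math.log(1.0 + (n_docs - doc_frequency + 0.5) / (doc_frequency + 0.5))


def bm25_term_score(
    tf: int, doc_length: int, avg_doc_length: float, idf: float, k1: float, b: float
) -> float:
    """One term's Okapi BM25 contribution to a document's score."""
    denom = tf + k1 * (1.0 - b + b * doc_length / avg_doc_length)
    return idf * tf * (k1 + 1.0) / denom


def search(
    index: Index,
    query_text: str,
    params: RetrievalParams | None = None,
) -> list[tuple[str, float]]:
    """Rank documents for a query.

    ``bm25`` mode sums Okapi BM25 term scores over documents containing at
    least one query token; descending score, ties broken by ascending doc
    id. ``boolean_recency`` mode keeps documents containing ALL query
    tokens, ordered by date descending then doc id. At most
    ``params.n_retrieved`` results are returned.
    """
    params = params or RetrievalParams()
    query_tokens = tokenize(
        query_text, stopwords=index.stopwords, stem=index.stem
    )
    if not query_tokens:
        raise RetrievalError(f"query {query_text!r} is empty after tokenization")

    if params.mode == "boolean_recency":
        return _boolean_recency(index, query_tokens, params.n_retrieved)

    scores: dict[str, float] = {}
    for token, count in _counts(query_tokens).items():
        plist = index.postings.get(token)
        if not plist:
            continue
        idf = bm25_idf(index.n_docs, len(plist))
        for doc_id, tf in plist:
            contribution = bm25_term_score(
                tf,
                index.doc_lengths[doc_id],
                index.avg_doc_length,
                idf,
                params.k1,
                params.b,
            )
            scores[doc_id] = scores.get(doc_id, 0.0) + count * contribution
    ranked = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return ranked[: params.n_retrieved]


def _counts(tokens: Sequence[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for token in tokens:
        counts[token] = counts.get(token, 0) + 1
    return counts


def _boolean_recency(
    index: Index, query_tokens: list[str], n_retrieved: int
) -> list[tuple[str, float]]:
    doc_sets = []
    for token in set(query_tokens):
        plist = index.postings.get(token)
        if not plist:
            return []
        doc_sets.append({doc_id for doc_id, _ in plist})
    candidates = set.intersection(*doc_sets)
    missing = [d for d in candidates if d not in index.dates]
    if missing:
        raise RetrievalError(
            "boolean_recency requires document dates; missing for "
            f"{sorted(missing)[:3]}..."
        )
    # newest first; equal dates break ties by ascending doc id
    ordered = sorted(candidates, key=lambda d: (_neg_date(index.dates[d]), d))
    return [(doc_id, 0.0) for doc_id in ordered[:n_retrieved]]


def _neg_date(d: date) -> tuple[int, int, int]:
    return (-d.year, -d.month, -d.day)
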