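"""Dictionary-based GO classifier.

Two components, combined: a vector-space component that indexes every GO
term's surface forms (name + synonyms) as if each term were a tiny document
and ranks terms by BM25 similarity to the input text (high recall), and a
pattern-matching component that recognizes terms whose surface form occurs
literally — as a contiguous token subsequence — in the text. Literally
recognized terms are boosted so that they always outrank purely
vector-space candidates; longer literal matches outrank shorter ones.

This family of classifiers can, by construction, only propose terms whose
wording overlaps the input text; its contrast with the supervised k-NN
classifier is the point of the deep-QA comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .ontology import Ontology, namespace_terms, normalize, surface_forms
from .retrieval import (
    Index,
    RetrievalError,
    RetrievalParams,
    build_index,
    search,
    tokenize,
)

__all__ = [
    "ScoredTerm",
    "TermIndex",
    "build_term_index",
    "vsm_rank",
    "literal_matches",
    "classify_dictionary",
]


@dataclass(frozen=True)
class ScoredTerm:
    """A ranked GO candidate produced by a classifier."""

    go_id: str
    score: float
    literal_match: bool = False
    match_length: int = 0


@dataclass
class TermIndex:
    """BM25 index over term pseudo-documents plus the raw token forms used
    for literal matching (literal matching keeps stopwords: 'regulation of
    growth' must match as written)."""

    index: Index
    go_ids: list[str]
    form_tokens: dict[str, list[tuple[str, ...]]]
    namespaces: frozenset[str]


def build_term_index(
    ontology: Ontology, namespaces: Iterable[str]
) -> TermIndex:
    """Index every non-obsolete term of the given namespaces under all its
    surface forms, concatenated into one pseudo-document per term."""
    namespaces = frozenset(namespaces)
    if not namespaces:
        raise ValueError("at least one namespace required")
    go_ids = sorted(
        set().union(*(namespace_terms(ontology, ns) for ns in namespaces))
    )
    texts: dict[str, str] = {}
    form_tokens: dict[str, list[tuple[str, ...]]] = {}
    for go_id in go_ids:
        forms = surface_forms(ontology, go_id)
        texts[go_id] = " ".join(forms)
        form_tokens[go_id] = [
            tuple(form.split()) for form in forms if form
        ]
    return TermIndex(
        index=build_index(texts),
        go_ids=go_ids,
        form_tokens=form_tokens,
        namespaces=namespaces,
    )


def vsm_rank(term_index: TermIndex, text: str) -> list[ScoredTerm]:
    """All terms with positive BM25 similarity to the text, descending
    score, ties by GO id."""
    if not tokenize(text):
        raise RetrievalError("text is empty after tokenization")
    params = RetrievalParams(n_retrieved=len(term_index.go_ids))
    hits = search(term_index.index, text, params)
    return [ScoredTerm(go_id=g, score=s) for g, s in hits if s > 0.0]


def literal_matches(
    term_index: TermIndex, text: str
) -> dict[str, int]:
    """Terms whose surface form occurs as a contiguous subsequence of the
    normalized token sequence of the text.

    Returns ``go_id -> match_length`` where match_length is the token count
    of the longest matching form. Matching is exact on normalized tokens:
    no gaps, no reordering, no partial-form credit.
    """
    text_tokens = tuple(normalize(text).split())
    if not text_tokens:
        return {}
    lengths_needed = {
        len(form)
        for forms in term_index.form_tokens.values()
        for form in forms
    }
    ngrams: dict[int, set[tuple[str, ...]]] = {}
    for n in lengths_needed:
        if n <= len(text_tokens):
            ngrams[n] = {
                text_tokens[i : i + n]
                for i in range(len(text_tokens) - n + 1)
            }
    matches: dict[str, int] = {}
    for go_id, forms in term_index.form_tokens.items():
        best = 0
        for form in forms:
            if len(form) > best and form in ngrams.get(len(form), ()):
                best = len(form)
        if best:
            matches[go_id] = best
    return matches


def classify_dictionary(
    term_index: TermIndex, text: str, m: int = 5
) -> list[ScoredTerm]:
    """Top-m terms under the combined score.

    final = vsm + B * match_length for literally matched terms, with the
    boost B = 1 + max vsm score chosen per call so literal matches dominate
    the ranking regardless of vector-space scores. Ties break by GO id.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    vsm = {st.go_id: st.score for st in vsm_rank(term_index, text)}
    matched = literal_matches(term_index, text)
    boost = 1.0 + (max(vsm.values()) if vsm else 0.0)
    scored = [
        ScoredTerm(
            go_id=go_id,
            score=vsm.get(go_id, 0.0) + boost * matched.get(go_id, 0),
            literal_match=go_id in matched,
            match_length=matched.get(go_id, 0),
        )
        for go_id in set(vsm) | set(matched)
    ]
    scored.sort(key=lambda st: (-st.score, st.go_id))
    return scored[:m]
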