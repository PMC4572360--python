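"""End-to-end deep question answering.

The pipeline has three stages, each replaceable:

1. a question categorizer maps a natural-language question onto a target
   GO namespace (the admissible answer set) and the reformulated query —
   the entity name — used for retrieval;
2. an information-retrieval component fetches up to 100 abstracts for the
   entity query (BM25 relevance ranking or Boolean/recency ordering);
3. each retrieved abstract is classified into top-m GO terms by a
   pluggable classifier (dictionary-based or supervised k-NN), and the
   per-abstract predictions are aggregated by citation counting: a
   candidate answer's score is the number of retrieved abstracts whose
   prediction list contains it. Macro-reading, in other words.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Protocol, Sequence

from .corpus_io import Document
from .dict_classifier import ScoredTerm, TermIndex, build_term_index, classify_dictionary
from .knn_classifier import KBIndex, classify_knn
from .ontology import Ontology, namespace_terms, resolve_id
from .retrieval import Index, RetrievalError, RetrievalParams, search, tokenize

__all__ = [
    "Question",
    "Answer",
    "AnswerSet",
    "QuestionError",
    "Classifier",
    "DictionaryClassifier",
    "KNNClassifier",
    "categorize_question",
    "macro_read",
    "answer",
    "write_answers",
]

logger = logging.getLogger(__name__)


class QuestionError(Exception):
    """Raised when no question template matches."""


@dataclass(frozen=True)
class Question:
    raw: str
    entity_query: str
    target_namespace: str


@dataclass(frozen=True)
class Answer:
    go_id: str
    citation_count: int
    supporting_pmids: tuple[str, ...]


@dataclass
class AnswerSet:
    question: Question
    answers: list[Answer]
    n_docs_used: int

    @property
    def ranked_ids(self) -> list[str]:
        return [a.go_id for a in self.answers]


# Template table mapping question scaffolds to target namespaces. The
# entity is whatever remains once the scaffold is removed; trailing
# punctuation is stripped. Unknown question forms fail loudly rather than
# guessing a namespace.
_TEMPLATES: list[tuple[re.Pattern[str], str]] = [
    (
        re.compile(
            r"^\s*what\s+molecular\s+functions?\s+"
            r"(?:(?:is|are)\s+)?(?:affected\s+by|associated\s+with|of)\s+"
            r"(?P<entity>.+?)\s*[?.!]*\s*$",
            re.IGNORECASE,
        ),
        "molecular_function",
    ),
    (
        re.compile(
            r"^\s*what\s+cellular\s+components?\s+"
            r"(?:(?:is|are)\s+the\s+locations?\s+of|of|contains?)\s+"
            r"(?P<entity>.+?)\s*[?.!]*\s*$",
            re.IGNORECASE,
        ),
        "cellular_component",
    ),
    (
        re.compile(
            r"^\s*what\s+biological\s+process(?:es)?\s+"
            r"(?:(?:is|are)\s+)?(?:affected\s+by|associated\s+with|"
            r"involving|of)\s+(?P<entity>.+?)\s*[?.!]*\s*$",
            re.IGNORECASE,
        ),
        "biological_process",
    ),
]


def categorize_question(text: str, ontology: Ontology) -> Question:
    """Map a question onto (entity query, target namespace).

    E.g. "what molecular functions are affected by Aminophenols ?" yields
    entity "Aminophenols" with the molecular_function axis as target set.
    """
    if not text.strip():
        raise QuestionError("empty question")
    for pattern, namespace in _TEMPLATES:
        match = pattern.match(text)
        if match is None:
            continue
        entity = match.group("entity").strip()
        if not entity:
            continue
        return Question(
            raw=text, entity_query=entity, target_namespace=namespace
        )
    raise QuestionError(f"unsupported question form: {text!r}")


class Classifier(Protocol):
    """Black-box per-abstract GO classifier.

    Returns the top-m scored terms of the given namespace for one
    document's text. Namespace restriction is applied before the top-m
    cutoff so off-axis terms never consume slots.
    """

    def classify(
        self, text: str, namespace: str, m: int
    ) -> Sequence[ScoredTerm]: ...


class DictionaryClassifier:
    """Adapter wrapping the dictionary classifier, one term index per
    namespace, built lazily."""

    name = "dict"

    def __init__(self, ontology: Ontology):
        self._ontology = ontology
        self._indexes: dict[str, TermIndex] = {}

    def term_index(self, namespace: str) -> TermIndex:
        if namespace not in self._indexes:
            self._indexes[namespace] = build_term_index(
                self._ontology, [namespace]
            )
        return self._indexes[namespace]

    def classify(self, text: str, namespace: str, m: int) -> list[ScoredTerm]:
        if not tokenize(text):
            return []
        return classify_dictionary(self.term_index(namespace), text, m)


class KNNClassifier:
    """Adapter wrapping the k-NN classifier over a knowledge-base index."""

    name = "knn"

    def __init__(
        self,
        kb_index: KBIndex,
        ontology: Ontology,
        k: int | None = None,
        exclude_pmids: Iterable[str] = (),
    ):
        self._kb_index = kb_index
        self._ontology = ontology
        self._k = k
        self._exclude = frozenset(exclude_pmids)

    def classify(self, text: str, namespace: str, m: int) -> list[ScoredTerm]:
        if not tokenize(text):
            return []
        return classify_knn(
            self._kb_index,
            text,
            k=self._k,
            m=m,
            exclude_pmids=self._exclude,
            namespace=namespace,
            ontology=self._ontology,
        )


def macro_read(
    per_doc_predictions: Iterable[tuple[str, Iterable[str | ScoredTerm]]],
    target_namespace: str,
    ontology: Ontology,
) -> list[Answer]:
    """Aggregate per-document predictions by citation counting.

    Each document contributes its prediction list as a set (a term cited
    twice in one document counts once); a candidate's score is the number
    of documents citing it. Candidates outside the target namespace are
    dropped. Sorted by count descending, GO id ascending.
    """
    allowed = namespace_terms(ontology, target_namespace)
    support: dict[str, list[str]] = {}
    for doc_id, predictions in per_doc_predictions:
        cited: set[str] = set()
        for pred in predictions:
            go_id = pred.go_id if isinstance(pred, ScoredTerm) else pred
            go_id = resolve_id(ontology, go_id)
            if go_id in allowed:
                cited.add(go_id)
        for go_id in cited:
            support.setdefault(go_id, []).append(doc_id)
    ordered = sorted(support, key=lambda g: (-len(support[g]), g))
    return [
        Answer(
            go_id=g,
            citation_count=len(support[g]),
            supporting_pmids=tuple(sorted(support[g])),
        )
        for g in ordered
    ]


def answer(
    question_text: str,
    index: Index,
    corpus: Mapping[str, Document],
    classifier: Classifier,
    ontology: Ontology,
    params: RetrievalParams | None = None,
    m: int = 5,
) -> AnswerSet:
    """Answer a natural-language question from the indexed corpus.

    Categorize -> retrieve up to ``params.n_retrieved`` abstracts for the
    entity query -> classify each into top-m terms of the target namespace
    -> count citations. Zero retrieved documents yields an empty answer
    set with a warning, not an error.
    """
    params = params or RetrievalParams()
    question = categorize_question(question_text, ontology)
    try:
        retrieved = search(index, question.entity_query, params)
    except RetrievalError:
        retrieved = []
    if not retrieved:
        logger.warning(
            "no documents retrieved for %r (query %r)",
            question_text,
            question.entity_query,
        )
        return AnswerSet(question=question, answers=[], n_docs_used=0)
    logger.info(
        "question %r: retrieved %d documents: %s",
        question_text,
        len(retrieved),
        [pmid for pmid, _ in retrieved],
    )
    predictions: list[tuple[str, list[ScoredTerm]]] = []
    for pmid, _score in retrieved:
        top = list(
            classifier.classify(
                corpus[pmid].full_text, question.target_namespace, m
            )
        )
        logger.debug(
            "doc %s -> %s", pmid, [(t.go_id, t.score) for t in top]
        )
        predictions.append((pmid, top))
    answers = macro_read(predictions, question.target_namespace, ontology)
    return AnswerSet(
        question=question, answers=answers, n_docs_used=len(retrieved)
    )


def write_answers(
    answer_set: AnswerSet, ontology: Ontology, stream: IO[str]
) -> None:
    """Write an answer set as TSV: rank, GO id, name, count, pmids."""
    stream.write("# " + answer_set.question.raw + "\n")
    stream.write("rank\tgo_id\tname\tcitation_count\tpmids\n")
    for rank, ans in enumerate(answer_set.answers, start=1):
        name = ontology.terms[ans.go_id].name
        pmids = ",".join(ans.supporting_pmids)
        stream.write(
            f"{rank}\t{ans.go_id}\t{name}\t{ans.citation_count}\t{pmids}\n"
        )
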