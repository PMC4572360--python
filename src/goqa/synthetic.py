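"""Synthetic ontology, corpus, knowledge base and QA benchmarks.

The generator emulates the statistical structure the method depends on,
without any downloads:

* a toy GO-style DAG per namespace (one root, preferential attachment,
  multi-word term names and synonyms);
* curated abstracts: each term receives ``docs_per_term`` documents
  annotated with it (plus a few co-annotations); a document's text mixes
  background tokens, the *topic tokens* of its annotated terms, and — with
  probability ``rho``, independently per annotation — the term's literal
  name. Topic tokens are disjoint from name tokens, so ``rho`` cleanly
  separates explicit (literally mentioned) from implicit evidence: at
  rho=0 an annotation is only ever recoverable through curated data, at
  rho=1 every annotation is literally on the page;
* QA benchmarks: entities with a gold set of same-namespace terms and
  ``docs_per_entity`` fresh (un-annotated) abstracts mentioning the entity
  plus the gold terms' topic tokens, with templated questions.

Entity documents additionally carry literal mentions of a few *general*
terms of the namespace (children of the root), mimicking how real
abstracts literally mention broad vocabulary terms that are not the
curated answer — the spurious matches that dominate dictionary-classifier
output. These distractor mentions are never drawn for gold terms, so the
rho construction invariants above are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .corpus_io import (
    Benchmark,
    BenchmarkEntry,
    Document,
    KnowledgeBase,
    write_benchmark,
    write_documents,
    write_gaf,
)
from .ontology import NAMESPACES, Ontology, Term, write_obo

__all__ = ["SynthConfig", "make_ontology", "make_corpus", "make_qa_benchmark",
           "write_dataset"]

_EVIDENCE_CODES = ("EXP", "IDA", "IMP", "TAS")

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu ka ke ki "
    "ko ku la le li lo lu ma me mi mo mu na ne ni no nu pa pe pi po pu ra "
    "re ri ro ru sa se si so su ta te ti to tu va ve vi vo vu za ze zi zo zu"
).split()


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters. Defaults are the core-experiment conditions.

    ``rho`` is the literal-mention probability: how often an annotated (or
    gold) term's name is written out verbatim in a document's text.
    ``docs_per_term`` (default 15) keeps every term above the ~10 curated
    abstracts usually considered the minimum to train a classifier on a
    class.
    """

    seed: int = 0
    n_terms: int = 20                 # per namespace, excluding the root
    max_extra_parents: int = 1        # a term has 1 + up to this many parents
    synonyms_per_term: int = 2
    topic_tokens_per_term: int = 6
    background_vocab_size: int = 200
    background_tokens_per_doc: int = 20
    rho: float = 0.1
    docs_per_term: int = 15
    max_extra_annotations: int = 3    # co-annotations per document
    n_questions: int = 30
    gold_per_question: tuple[int, int] = (1, 3)
    docs_per_entity: int = 20
    gold_inclusion_prob: float = 0.7  # per entity doc, per gold term
    common_terms_per_namespace: int = 4
    common_mention_prob: float = 0.3  # distractor literal mentions
    obsolete_per_namespace: int = 0
    first_pmid: int = 1000000
    entity_pmid_base: int = 2000000
    date_range: tuple[int, int] = (2000, 2015)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        for name in (
            "n_terms", "synonyms_per_term", "topic_tokens_per_term",
            "background_vocab_size", "background_tokens_per_doc",
            "docs_per_term", "n_questions", "docs_per_entity",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class _Vocabulary:
    """Disjoint token pools (derived deterministically from the seed):
    name tokens per namespace, per-term topic tokens, background words and
    entity names. Disjointness is what lets rho separate explicit from
    implicit evidence."""

    name_tokens: dict[str, list[str]]
    topic_tokens: dict[str, list[str]]  # term id -> tokens
    background: list[str]
    entities: list[str]


def _unique_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < n:
        size = int(rng.integers(2, 5))
        word = "".join(
            _SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), size)
        )
        if word in taken or len(word) < 4:
            continue
        taken.add(word)
        words.append(word)
    return words


def _term_ids(config: SynthConfig) -> dict[str, list[str]]:
    """Deterministic id layout: per namespace, root first, then terms."""
    ids: dict[str, list[str]] = {}
    counter = 1
    per_ns = 1 + config.n_terms + config.obsolete_per_namespace
    for namespace in NAMESPACES:
        ids[namespace] = [f"GO:{counter + i:07d}" for i in range(per_ns)]
        counter += per_ns
    return ids


def _vocabulary(config: SynthConfig) -> _Vocabulary:
    rng = np.random.default_rng([config.seed, 0])
    taken: set[str] = set()
    ids = _term_ids(config)
    name_tokens = {
        ns: _unique_words(rng, 4 * config.n_terms + 8, taken)
        for ns in NAMESPACES
    }
    topic_tokens: dict[str, list[str]] = {}
    for ns in NAMESPACES:
        for term_id in ids[ns]:
            topic_tokens[term_id] = _unique_words(
                rng, config.topic_tokens_per_term, taken
            )
    background = _unique_words(rng, config.background_vocab_size, taken)
    entities = _unique_words(rng, config.n_questions, taken)
    return _Vocabulary(
        name_tokens=name_tokens,
        topic_tokens=topic_tokens,
        background=background,
        entities=entities,
    )


def _phrase(
    rng: np.random.Generator, pool: list[str], used: set[str]
) -> str:
    while True:
        size = int(rng.integers(2, 4))
        idx = rng.choice(len(pool), size=size, replace=False)
        phrase = " ".join(pool[int(i)] for i in idx)
        if phrase not in used:
            used.add(phrase)
            return phrase


def make_ontology(config: SynthConfig) -> Ontology:
    """Generate one rooted DAG per namespace with multi-word names,
    synonyms, occasional alt_ids, writable as OBO."""
    rng = np.random.default_rng([config.seed, 1])
    vocab = _vocabulary(config)
    ids = _term_ids(config)
    terms: dict[str, Term] = {}
    alt_counter = 1
    for namespace in NAMESPACES:
        ns_ids = ids[namespace]
        root_id = ns_ids[0]
        terms[root_id] = Term(
            id=root_id,
            name=namespace.replace("_", " "),
            namespace=namespace,
        )
        used_phrases: set[str] = set()
        child_counts = {root_id: 0}
        for i, term_id in enumerate(ns_ids[1 : 1 + config.n_terms]):
            existing = ns_ids[: 1 + i]
            weights = np.array(
                [1.0 + child_counts[t] for t in existing], dtype=float
            )
            n_parents = 1 + int(
                rng.integers(0, config.max_extra_parents + 1)
            )
            n_parents = min(n_parents, len(existing))
            chosen = rng.choice(
                len(existing),
                size=n_parents,
                replace=False,
                p=weights / weights.sum(),
            )
            parents = tuple(sorted(existing[int(c)] for c in chosen))
            for parent in parents:
                child_counts[parent] += 1
            child_counts[term_id] = 0
            name = _phrase(rng, vocab.name_tokens[namespace], used_phrases)
            synonyms = tuple(
                _phrase(rng, vocab.name_tokens[namespace], used_phrases)
                for _ in range(config.synonyms_per_term)
            )
            scopes = tuple(
                "EXACT" if j % 2 == 0 else "RELATED"
                for j in range(len(synonyms))
            )
            alt_ids: tuple[str, ...] = ()
            if i % 7 == 3:
                alt_ids = (f"GO:{9000000 + alt_counter:07d}",)
                alt_counter += 1
            terms[term_id] = Term(
                id=term_id,
                name=name,
                namespace=namespace,
                synonyms=synonyms,
                synonym_scopes=scopes,
                parents=parents,
                alt_ids=alt_ids,
            )
        for term_id in ns_ids[1 + config.n_terms :]:
            terms[term_id] = Term(
                id=term_id,
                name=_phrase(rng, vocab.name_tokens[namespace], used_phrases),
                namespace=namespace,
                obsolete=True,
            )
    return Ontology(terms=terms)


def _random_date(rng: np.random.Generator, config: SynthConfig) -> date:
    start = date(config.date_range[0], 1, 1)
    end = date(config.date_range[1], 12, 31)
    offset = int(rng.integers(0, (end - start).days + 1))
    return start + timedelta(days=offset)


def _doc_text(
    rng: np.random.Generator,
    config: SynthConfig,
    vocab: _Vocabulary,
    ontology: Ontology,
    topic_terms: list[str],
    literal_terms: list[str],
    extra_tokens: list[str] | None = None,
) -> tuple[str, str]:
    """Assemble (title, text): shuffled background + topic tokens, then
    literal names spliced in as contiguous phrases."""
    n_bg = config.background_tokens_per_doc
    bg_idx = rng.integers(0, len(vocab.background), n_bg + 3)
    title = " ".join(vocab.background[int(i)] for i in bg_idx[:3])
    body = [vocab.background[int(i)] for i in bg_idx[3:]]
    for term_id in topic_terms:
        body.extend(vocab.topic_tokens[term_id])
    if extra_tokens:
        body.extend(extra_tokens)
    rng.shuffle(body)
    # literal names are spliced in as atomic phrases so that a later
    # insertion can never break an earlier one's contiguity
    elements: list[str] = list(body)
    for term_id in literal_terms:
        pos = int(rng.integers(0, len(elements) + 1))
        elements.insert(pos, ontology.terms[term_id].name)
    return title, " ".join(elements)


def _annotatable(ontology: Ontology) -> list[str]:
    roots = set(ontology.roots.values())
    return sorted(
        t.id
        for t in ontology.terms.values()
        if not t.obsolete and t.id not in roots
    )


def make_corpus(
    config: SynthConfig, ontology: Ontology
) -> tuple[dict[str, Document], KnowledgeBase]:
    """Curated corpus: ``docs_per_term`` documents per (non-root) term,
    each annotated with 1-4 terms, text built per the rho construction."""
    rng = np.random.default_rng([config.seed, 2])
    vocab = _vocabulary(config)
    term_ids = _annotatable(ontology)
    corpus: dict[str, Document] = {}
    kb = KnowledgeBase()
    pmid_counter = config.first_pmid
    for term_id in term_ids:
        for _ in range(config.docs_per_term):
            n_extra = int(rng.integers(0, config.max_extra_annotations + 1))
            others = [t for t in term_ids if t != term_id]
            extra_idx = rng.choice(len(others), size=n_extra, replace=False)
            annotations = [term_id] + sorted(others[int(i)] for i in extra_idx)
            literal = [t for t in annotations if rng.random() < config.rho]
            title, text = _doc_text(
                rng, config, vocab, ontology, annotations, literal
            )
            pmid = str(pmid_counter)
            pmid_counter += 1
            corpus[pmid] = Document(
                pmid=pmid,
                title=title,
                text=text,
                date=_random_date(rng, config),
            )
            evidence = _EVIDENCE_CODES[
                int(rng.integers(0, len(_EVIDENCE_CODES)))
            ]
            for go_id in annotations:
                kb.add(pmid, go_id, evidence)
    return corpus, kb


def _common_terms(ontology: Ontology, config: SynthConfig) -> dict[str, list[str]]:
    """Per namespace: the general terms (children of the root, by id) used
    as distractor literal mentions."""
    out: dict[str, list[str]] = {}
    for namespace, root in ontology.roots.items():
        children = sorted(
            t.id
            for t in ontology.terms.values()
            if not t.obsolete and root in t.parents
        )
        if len(children) < config.common_terms_per_namespace:
            extra = [
                t
                for t in _annotatable(ontology)
                if ontology.terms[t].namespace == namespace
                and t not in children
            ]
            children.extend(
                extra[: config.common_terms_per_namespace - len(children)]
            )
        out[namespace] = children[: config.common_terms_per_namespace]
    return out


_QUESTION_TEMPLATES = {
    "molecular_function": "what molecular functions are affected by {entity} ?",
    "cellular_component": "what cellular component is the location of {entity}?",
    "biological_process": "what biological processes are affected by {entity} ?",
}


def make_qa_benchmark(
    config: SynthConfig,
    ontology: Ontology,
    corpus: dict[str, Document],
) -> tuple[Benchmark, dict[str, Document]]:
    """Templated questions plus fresh entity documents.

    Questions alternate between the molecular_function and
    cellular_component axes (the two benchmark styles: chemical->function
    and protein->location). Each entity's documents evoke a random subset
    of its gold terms through topic tokens; literal gold-term names appear
    with probability rho, distractor general-term names with probability
    ``common_mention_prob``. Entity documents are not annotated (they play
    the role of freshly retrieved abstracts).
    """
    rng = np.random.default_rng([config.seed, 3])
    vocab = _vocabulary(config)
    common = _common_terms(ontology, config)
    lo, hi = config.gold_per_question
    entries: list[BenchmarkEntry] = []
    extended = dict(corpus)
    question_namespaces = ("molecular_function", "cellular_component")
    for q in range(config.n_questions):
        namespace = question_namespaces[q % 2]
        eligible = [
            t
            for t in _annotatable(ontology)
            if ontology.terms[t].namespace == namespace
            and t not in common[namespace]
        ]
        gold_size = int(rng.integers(lo, hi + 1))
        if gold_size > len(eligible):
            raise ValueError(
                f"gold set size {gold_size} exceeds the {len(eligible)} "
                f"eligible {namespace} terms"
            )
        gold_idx = rng.choice(len(eligible), size=gold_size, replace=False)
        gold = sorted(eligible[int(i)] for i in gold_idx)
        entity = vocab.entities[q].capitalize()
        for d in range(config.docs_per_entity):
            included = [
                t for t in gold if rng.random() < config.gold_inclusion_prob
            ]
            if not included:
                included = [gold[int(rng.integers(0, len(gold)))]]
            literal = [t for t in included if rng.random() < config.rho]
            distractors = [
                t
                for t in common[namespace]
                if t not in gold and rng.random() < config.common_mention_prob
            ]
            title, text = _doc_text(
                rng,
                config,
                vocab,
                ontology,
                included,
                literal + distractors,
                extra_tokens=[entity.lower()],
            )
            pmid = str(config.entity_pmid_base + q * config.docs_per_entity + d)
            extended[pmid] = Document(
                pmid=pmid,
                title=title,
                text=text,
                date=_random_date(rng, config),
            )
        entries.append(
            BenchmarkEntry(
                question=_QUESTION_TEMPLATES[namespace].format(entity=entity),
                entity=entity,
                namespace=namespace,
                gold=frozenset(gold),
            )
        )
    return Benchmark(entries=entries), extended


def write_dataset(
    config: SynthConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate everything and write the four external formats to a
    directory: ontology.obo, annotations.gaf, corpus.jsonl (including the
    entity documents), benchmark.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ontology = make_ontology(config)
    corpus, kb = make_corpus(config, ontology)
    benchmark, extended = make_qa_benchmark(config, ontology, corpus)
    paths = {
        "obo": out / "ontology.obo",
        "gaf": out / "annotations.gaf",
        "corpus": out / "corpus.jsonl",
        "benchmark": out / "benchmark.tsv",
    }
    with paths["obo"].open("w") as fh:
        write_obo(ontology, fh)
    with paths["gaf"].open("w") as fh:
        write_gaf(kb, fh)
    with paths["corpus"].open("w") as fh:
        write_documents(extended, fh)
    with paths["benchmark"].open("w") as fh:
        write_benchmark(benchmark, fh)
    return paths
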