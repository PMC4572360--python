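"""Corpus, annotation and benchmark I/O.

Three external artifacts feed the pipeline:

* an abstract corpus as JSON Lines — one object per line with keys
  ``pmid``, ``title``, ``text`` and optional ``date`` (ISO 8601);
* a curated annotation knowledge base in GAF 2.x (tab-separated; the
  literature reference column keys annotations to PMIDs);
* question benchmarks as TSV: question text, entity, target namespace,
  semicolon-joined gold GO ids.

The knowledge base is what the supervised classifier votes over; its
``hold_out`` supports the leave-out protocol in which the documents being
classified are removed from the classifier's training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import IO, Iterable, Mapping

import numpy as np

from .ontology import (
    GO_ID_RE,
    NAMESPACES,
    Ontology,
    UnknownIdentifierError,
    namespace_terms,
    resolve_id,
)

__all__ = [
    "Document",
    "KnowledgeBase",
    "Benchmark",
    "BenchmarkEntry",
    "CorpusFormatError",
    "DEFAULT_EVIDENCE_EXCLUDED",
    "read_documents",
    "write_documents",
    "read_gaf",
    "write_gaf",
    "hold_out",
    "build_micro_benchmark",
    "read_benchmark",
    "write_benchmark",
]

logger = logging.getLogger(__name__)

# "Manually curated" is operationalized as everything except electronic
# (IEA) annotations; the exact curated-code set is configurable because
# annotation practice varies between GOA releases.
DEFAULT_EVIDENCE_EXCLUDED = frozenset({"IEA"})


class CorpusFormatError(Exception):
    """Raised on malformed corpus / GAF / benchmark input."""


@dataclass(frozen=True)
class Document:
    """One abstract: the unit of micro-reading."""

    pmid: str
    title: str
    text: str
    date: date | None = None

    @property
    def full_text(self) -> str:
        """Title + abstract, the granularity used for similarity."""
        return f"{self.title} {self.text}".strip()


@dataclass
class KnowledgeBase:
    """pmid -> curated primary GO ids, with per-pair evidence codes."""

    annotations: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.annotations)

    def __contains__(self, pmid: str) -> bool:
        return pmid in self.annotations

    def add(self, pmid: str, go_id: str, evidence: str = "TAS") -> None:
        self.annotations.setdefault(pmid, set()).add(go_id)
        self.provenance.setdefault((pmid, go_id), evidence)


@dataclass(frozen=True)
class BenchmarkEntry:
    question: str
    entity: str
    namespace: str
    gold: frozenset[str]


@dataclass
class Benchmark:
    entries: list[BenchmarkEntry]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# document corpus (JSONL)

def read_documents(stream: IO[str] | Iterable[str]) -> dict[str, Document]:
    """Read a JSONL corpus into an ordered ``pmid -> Document`` mapping.

    Duplicate pmids: last record wins, with a logged warning. Malformed
    records raise :class:`CorpusFormatError` naming the line number.
    """
    corpus: dict[str, Document] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            record = json.loads(line)
            pmid = str(record["pmid"])
            title = record["title"]
            text = record["text"]
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise CorpusFormatError(
                f"line {lineno}: malformed document record ({exc})"
            ) from exc
        doc_date = None
        if record.get("date"):
            try:
                doc_date = date.fromisoformat(record["date"])
            except ValueError as exc:
                raise CorpusFormatError(
                    f"line {lineno}: bad date {record['date']!r}"
                ) from exc
        if pmid in corpus:
            logger.warning("duplicate pmid %s at line %d; keeping last", pmid, lineno)
            del corpus[pmid]  # reinsert so the last record also takes last position
        corpus[pmid] = Document(pmid=pmid, title=title, text=text, date=doc_date)
    return corpus


def write_documents(corpus: Mapping[str, Document], stream: IO[str]) -> None:
    for doc in corpus.values():
        record: dict[str, str] = {
            "pmid": doc.pmid,
            "title": doc.title,
            "text": doc.text,
        }
        if doc.date is not None:
            record["date"] = doc.date.isoformat()
        stream.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# GAF annotations

def _pmid_from_reference(reference: str) -> str | None:
    for ref in reference.split("|"):
        if ref.startswith("PMID:"):
            return ref[len("PMID:"):]
    return None


def read_gaf(
    stream: IO[str] | Iterable[str],
    ontology: Ontology,
    evidence_filter: frozenset[str] | set[str] | None = None,
) -> KnowledgeBase:
    """Read GAF 2.x rows into a literature-keyed knowledge base.

    ``evidence_filter`` is the set of evidence codes to KEEP; ``None`` keeps
    every code except IEA. Rows are dropped when they carry a NOT
    qualifier, lack a PMID reference, or fail the evidence filter; rows
    with a non-GO or unresolvable ontology id are skipped with a warning.
    GO ids are resolved to primary ids through alt_id mapping.
    """
    kb = KnowledgeBase()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 7:
            raise CorpusFormatError(
                f"line {lineno}: GAF row has {len(cols)} columns, expected >= 7"
            )
        qualifier, go_id, reference, evidence = cols[3], cols[4], cols[5], cols[6]
        if "NOT" in qualifier.split("|"):
            continue
        if evidence_filter is None:
            if evidence in DEFAULT_EVIDENCE_EXCLUDED:
                continue
        elif evidence not in evidence_filter:
            continue
        pmid = _pmid_from_reference(reference)
        if pmid is None:
            continue
        if not GO_ID_RE.match(go_id):
            logger.warning("line %d: skipping non-GO id %r", lineno, go_id)
            continue
        try:
            primary = resolve_id(ontology, go_id)
        except UnknownIdentifierError:
            logger.warning("line %d: skipping unresolvable id %s", lineno, go_id)
            continue
        kb.add(pmid, primary, evidence)
    return kb


def write_gaf(kb: KnowledgeBase, stream: IO[str], db: str = "GOA") -> None:
    """Write the knowledge base as minimal GAF 2.1 rows."""
    stream.write("!gaf-version: 2.1\n")
    for pmid in sorted(kb.annotations, key=_pmid_sort_key):
        for go_id in sorted(kb.annotations[pmid]):
            evidence = kb.provenance.get((pmid, go_id), "TAS")
            cols = [
                db, f"OBJ:{pmid}", f"obj{pmid}", "", go_id, f"PMID:{pmid}",
                evidence, "", "P", "", "", "protein", "taxon:9606",
                "20150101", db, "", "",
            ]
            stream.write("\t".join(cols) + "\n")


def _pmid_sort_key(pmid: str) -> tuple[int, str]:
    return (0, pmid.zfill(16)) if pmid.isdigit() else (1, pmid)


def hold_out(kb: KnowledgeBase, pmids: Iterable[str]) -> KnowledgeBase:
    """A copy of the knowledge base without the listed pmids.

    This is the leave-out protocol: documents about to be classified are
    discarded from the classifier's training data so a document can never
    vote for itself. Absent pmids are ignored; the input is unmodified.
    """
    excluded = set(pmids)
    out = KnowledgeBase()
    for pmid, gold in kb.annotations.items():
        if pmid in excluded:
            continue
        out.annotations[pmid] = set(gold)
        for go_id in gold:
            key = (pmid, go_id)
            if key in kb.provenance:
                out.provenance[key] = kb.provenance[key]
    return out


# ---------------------------------------------------------------------------
# micro benchmark

def build_micro_benchmark(
    kb: KnowledgeBase,
    corpus: Mapping[str, Document],
    n: int,
    seed: int,
) -> list[tuple[Document, set[str]]]:
    """Uniform sample (without replacement) of n annotated abstracts.

    The gold standard for each abstract is its curated annotation set; this
    is the micro-reading benchmark construction.
    """
    available = sorted(set(kb.annotations) & set(corpus), key=_pmid_sort_key)
    if n > len(available):
        raise ValueError(
            f"requested {n} abstracts but only {len(available)} are both "
            "annotated and present in the corpus"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(available), size=n, replace=False)
    return [
        (corpus[available[i]], set(kb.annotations[available[i]]))
        for i in sorted(chosen)
    ]


# ---------------------------------------------------------------------------
# question benchmarks (TSV)

def read_benchmark(
    stream: IO[str] | Iterable[str], ontology: Ontology
) -> Benchmark:
    """Read and validate a question benchmark.

    Every gold id must resolve in the ontology and belong to the entry's
    target namespace (strict-ID evaluation presumes a clean gold file).
    """
    entries: list[BenchmarkEntry] = []
    allowed: dict[str, set[str]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise CorpusFormatError(
                f"line {lineno}: expected 4 tab-separated fields, got {len(cols)}"
            )
        question, entity, namespace, gold_field = cols
        if namespace not in NAMESPACES:
            raise CorpusFormatError(
                f"line {lineno}: unknown namespace {namespace!r}"
            )
        gold_ids = [g for g in gold_field.split(";") if g]
        if not gold_ids:
            raise CorpusFormatError(
                f"line {lineno} ({question!r}): empty gold set"
            )
        if namespace not in allowed:
            allowed[namespace] = namespace_terms(ontology, namespace)
        resolved: set[str] = set()
        for go_id in gold_ids:
            try:
                primary = resolve_id(ontology, go_id)
            except UnknownIdentifierError as exc:
                raise CorpusFormatError(
                    f"line {lineno} ({question!r}): unknown gold id {go_id}"
                ) from exc
            if primary not in allowed[namespace]:
                raise CorpusFormatError(
                    f"line {lineno} ({question!r}): gold id {go_id} is not a "
                    f"{namespace} term"
                )
            resolved.add(primary)
        entries.append(
            BenchmarkEntry(
                question=question,
                entity=entity,
                namespace=namespace,
                gold=frozenset(resolved),
            )
        )
    return Benchmark(entries=entries)


def write_benchmark(benchmark: Benchmark, stream: IO[str]) -> None:
    for entry in benchmark.entries:
        gold = ";".join(sorted(entry.gold))
        stream.write(
            f"{entry.question}\t{entry.entity}\t{entry.namespace}\t{gold}\n"
        )
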