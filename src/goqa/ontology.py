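"""GO-style ontology handling: OBO parsing/writing, alt-id resolution,
graph levels, and the surface forms used by dictionary classification.

The ontology is the answer space of the QA system: each of the three Gene
Ontology namespaces (molecular_function, cellular_component,
biological_process) is a rooted DAG of terms connected by ``is_a`` edges.
Only ``is_a`` edges are modelled; ``part_of`` and other relationship types
are ignored.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

__all__ = [
    "NAMESPACES",
    "GO_ID_RE",
    "Term",
    "Ontology",
    "OntologyError",
    "OboParseError",
    "UnknownIdentifierError",
    "normalize",
    "parse_obo",
    "write_obo",
    "resolve_id",
    "go_level",
    "surface_forms",
    "namespace_terms",
]

NAMESPACES = ("molecular_function", "cellular_component", "biological_process")

GO_ID_RE = re.compile(r"GO:\d{7}$")

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z]+)?')

# Keep word characters, hyphens and slashes: GO names contain tokens like
# "serine/threonine" and "beta-galactosidase" that must stay intact.
_NORM_STRIP_RE = re.compile(r"[^\w/\-]+")


class OntologyError(Exception):
    """Base class for ontology errors."""


class OboParseError(OntologyError):
    """Raised when an OBO stream violates the format or the DAG invariants."""


class UnknownIdentifierError(OntologyError, KeyError):
    """Raised when an identifier is neither a primary id nor an alt_id."""


def normalize(text: str) -> str:
    """Normalize a string for matching: NFKC, lowercase, punctuation (except
    hyphen and slash) replaced by whitespace, whitespace collapsed."""
    text = unicodedata.normalize("NFKC", text).lower()
    text = _NORM_STRIP_RE.sub(" ", text)
    return " ".join(text.split())


@dataclass(frozen=True)
class Term:
    """One ontology term.

    ``synonym_scopes`` parallels ``synonyms`` (EXACT/BROAD/NARROW/RELATED);
    all scopes are indexed as surface forms, the scope is metadata only.
    """

    id: str
    name: str
    namespace: str
    synonyms: tuple[str, ...] = ()
    synonym_scopes: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()
    alt_ids: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass
class Ontology:
    """A validated set of terms with per-namespace roots and an alt-id map."""

    terms: dict[str, Term]
    roots: dict[str, str] = field(default_factory=dict)
    _alt: dict[str, str] = field(default_factory=dict, repr=False)
    _levels: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._alt:
            for term in self.terms.values():
                for alt in term.alt_ids:
                    if alt in self.terms:
                        raise OboParseError(
                            f"alt_id {alt} collides with a primary id"
                        )
                    if alt in self._alt and self._alt[alt] != term.id:
                        raise OboParseError(
                            f"alt_id {alt} claimed by both "
                            f"{self._alt[alt]} and {term.id}"
                        )
                    self._alt[alt] = term.id
        if not self.roots:
            self.roots = _find_roots(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> Term:
        return self.terms[resolve_id(self, term_id)]


def _find_roots(terms: Mapping[str, Term]) -> dict[str, str]:
    roots: dict[str, str] = {}
    for term in terms.values():
        if term.obsolete or term.parents:
            continue
        if term.namespace in roots:
            raise OboParseError(
                f"namespace {term.namespace} has two roots: "
                f"{roots[term.namespace]} and {term.id}"
            )
        roots[term.namespace] = term.id
    return roots


def _validate(terms: Mapping[str, Term]) -> None:
    graph = nx.DiGraph()
    for term in terms.values():
        graph.add_node(term.id)
        for parent in term.parents:
            if parent not in terms:
                raise OboParseError(
                    f"term {term.id} has is_a target {parent} "
                    "absent from the ontology"
                )
            if terms[parent].namespace != term.namespace:
                raise OboParseError(
                    f"term {term.id} ({term.namespace}) has parent {parent} "
                    f"in a different namespace ({terms[parent].namespace})"
                )
            graph.add_edge(term.id, parent)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        return
    child, parent = cycle[0][0], cycle[0][1]
    raise OboParseError(f"is_a cycle detected through edge {child} -> {parent}")


def _parse_stanza(
    lines: list[tuple[int, str]],
) -> Term:
    fields: dict[str, list[str]] = {}
    for lineno, line in lines:
        if ":" not in line:
            raise OboParseError(f"line {lineno}: malformed tag line {line!r}")
        tag, _, value = line.partition(":")
        # strip trailing OBO comments ("! ...") outside quoted strings
        if "!" in value and tag.strip() != "synonym":
            value = value.split("!", 1)[0]
        fields.setdefault(tag.strip(), []).append(value.strip())

    first_lineno = lines[0][0]
    if "id" not in fields:
        raise OboParseError(f"line {first_lineno}: [Term] stanza without id")
    term_id = fields["id"][0]
    obsolete = fields.get("is_obsolete", ["false"])[0].lower() == "true"
    if "name" not in fields:
        raise OboParseError(f"term {term_id}: missing name")
    if "namespace" not in fields:
        raise OboParseError(f"term {term_id}: missing namespace")
    namespace = fields["namespace"][0]
    if namespace not in NAMESPACES:
        raise OboParseError(f"term {term_id}: unknown namespace {namespace!r}")

    synonyms: list[str] = []
    scopes: list[str] = []
    for raw in fields.get("synonym", ()):
        match = _SYNONYM_RE.match(raw)
        if match is None:
            raise OboParseError(f"term {term_id}: malformed synonym {raw!r}")
        synonyms.append(match.group("text").replace('\\"', '"'))
        scopes.append(match.group("scope") or "RELATED")

    return Term(
        id=term_id,
        name=fields["name"][0],
        namespace=namespace,
        synonyms=tuple(synonyms),
        synonym_scopes=tuple(scopes),
        parents=tuple(fields.get("is_a", ())),
        alt_ids=tuple(fields.get("alt_id", ())),
        obsolete=obsolete,
    )


def parse_obo(stream: IO[str] | Iterable[str]) -> Ontology:
    """Parse an OBO 1.2-dialect stream of ``[Term]`` stanzas.

    Obsolete terms are loaded but flagged (they carry no is_a edges and are
    excluded from namespace queries). Acyclicity, dangling is_a targets and
    namespace consistency are verified; violations raise
    :class:`OboParseError`.
    """
    terms: dict[str, Term] = {}
    stanza: list[tuple[int, str]] = []
    in_term = False

    def flush() -> None:
        if not stanza:
            return
        term = _parse_stanza(stanza)
        if term.id in terms:
            raise OboParseError(f"duplicate term id {term.id}")
        terms[term.id] = term
        stanza.clear()

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            continue
        if not line or not in_term:
            continue
        stanza.append((lineno, line))
    flush()

    if not terms:
        raise OboParseError("no [Term] stanzas found")
    _validate(terms)
    return Ontology(terms=terms)


def write_obo(ontology: Ontology, stream: IO[str]) -> None:
    """Write the ontology as OBO 1.2 text; round-trips through parse_obo."""
    stream.write("format-version: 1.2\n")
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        stream.write(f"name: {term.name}\n")
        stream.write(f"namespace: {term.namespace}\n")
        for alt in term.alt_ids:
            stream.write(f"alt_id: {alt}\n")
        for syn, scope in zip(term.synonyms, term.synonym_scopes):
            escaped = syn.replace('"', '\\"')
            stream.write(f'synonym: "{escaped}" {scope} []\n')
        for parent in term.parents:
            stream.write(f"is_a: {parent} ! {ontology.terms[parent].name}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")


def resolve_id(ontology: Ontology, term_id: str) -> str:
    """Return the primary id for ``term_id`` (identity for primary ids,
    owner for alt_ids)."""
    if term_id in ontology.terms:
        return term_id
    if term_id in ontology._alt:
        return ontology._alt[term_id]
    raise UnknownIdentifierError(term_id)


def go_level(ontology: Ontology, term_id: str) -> int:
    """Depth of a term: the number of edges on the LONGEST is_a path from
    its namespace root (root level = 0).

    The longest-path convention makes levels monotone in the DAG:
    level(child) >= 1 + max(level(parent) for parents).
    """
    term_id = resolve_id(ontology, term_id)
    term = ontology.terms[term_id]
    if term.obsolete:
        raise OntologyError(f"term {term_id} is obsolete and has no level")
    levels = ontology._levels
    if term_id in levels:
        return levels[term_id]
    # iterative DFS with memoization; recursion would overflow on deep GO
    stack = [term_id]
    while stack:
        current = stack[-1]
        parents = ontology.terms[current].parents
        pending = [p for p in parents if p not in levels]
        if pending:
            stack.extend(pending)
            continue
        stack.pop()
        if current not in levels:
            levels[current] = (
                1 + max(levels[p] for p in parents) if parents else 0
            )
    return levels[term_id]


def surface_forms(ontology: Ontology, term_id: str) -> list[str]:
    """Normalized name + synonyms of a term, deduplicated, name first."""
    term = ontology.terms[resolve_id(ontology, term_id)]
    if term.obsolete:
        raise OntologyError(f"term {term.id} is obsolete")
    forms: list[str] = []
    seen: set[str] = set()
    for raw in (term.name, *term.synonyms):
        norm = normalize(raw)
        if norm and norm not in seen:
            seen.add(norm)
            forms.append(norm)
    return forms


def namespace_terms(ontology: Ontology, namespace: str) -> set[str]:
    """All non-obsolete term ids in a namespace — the admissible answer set
    (the "target set") for questions on that GO axis."""
    if namespace not in NAMESPACES:
        raise OntologyError(f"unknown namespace {namespace!r}")
    return {
        t.id
        for t in ontology.terms.values()
        if t.namespace == namespace and not t.obsolete
    }
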