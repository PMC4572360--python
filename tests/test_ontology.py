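import io

import networkx as nx
import obonet
import pytest

from goqa.ontology import (
    NAMESPACES,
    OboParseError,
    OntologyError,
    UnknownIdentifierError,
    go_level,
    namespace_terms,
    normalize,
    parse_obo,
    resolve_id,
    surface_forms,
    write_obo,
)
from goqa.synthetic import SynthConfig, make_ontology

from conftest import TINY_OBO


class TestParseObo:
    def test_three_stanza_fixture(self, tiny_ontology):
        assert len(tiny_ontology) == 3
        assert tiny_ontology.roots == {"molecular_function": "GO:0000001"}
        assert tiny_ontology.terms["GO:0000003"].parents == ("GO:0000002",)

    def test_obsolete_term_loaded_but_excluded(self, mixed_ontology):
        assert mixed_ontology.terms["GO:0000013"].obsolete
        assert "GO:0000013" not in namespace_terms(
            mixed_ontology, "cellular_component"
        )

    @pytest.mark.parametrize(
        "mutation, message",
        [
            ("is_a: GO:0009999", "absent"),
            ("", "missing namespace"),
        ],
    )
    def test_hard_errors(self, mutation, message):
        if message == "missing namespace":
            text = "[Term]\nid: GO:0000001\nname: lonely\n"
        else:
            text = TINY_OBO + mutation + "\n"
        with pytest.raises(OboParseError, match=message):
            parse_obo(io.StringIO(text))

    def test_cycle_detected_names_an_edge(self):
        text = """\
[Term]
id: GO:0000001
name: a
namespace: molecular_function
is_a: GO:0000002

[Term]
id: GO:0000002
name: b
namespace: molecular_function
is_a: GO:0000001
"""
        with pytest.raises(OboParseError, match="cycle"):
            parse_obo(io.StringIO(text))

    def test_cross_namespace_parent_rejected(self):
        text = """\
[Term]
id: GO:0000001
name: a
namespace: molecular_function

[Term]
id: GO:0000002
name: b
namespace: cellular_component
is_a: GO:0000001
"""
        with pytest.raises(OboParseError, match="namespace"):
            parse_obo(io.StringIO(text))


class TestResolveId:
    def test_primary_identity(self, tiny_ontology):
        assert resolve_id(tiny_ontology, "GO:0000002") == "GO:0000002"

    def test_alt_id_maps_to_owner(self, tiny_ontology):
        assert resolve_id(tiny_ontology, "GO:9000002") == "GO:0000002"

    def test_unknown_id_errors(self, tiny_ontology):
        with pytest.raises(UnknownIdentifierError):
            resolve_id(tiny_ontology, "GO:9999999")


class TestGoLevel:
    def test_root_is_level_zero(self, tiny_ontology):
        assert go_level(tiny_ontology, "GO:0000001") == 0

    def test_longest_path_in_diamond(self, diamond_ontology):
        # root -> A -> B and root -> B: the longest path to B has 2 edges
        assert go_level(diamond_ontology, "GO:0000003") == 2

    def test_obsolete_term_errors(self, mixed_ontology):
        with pytest.raises(OntologyError):
            go_level(mixed_ontology, "GO:0000013")

    def test_monotone_under_longest_path(self, synth_ontology):
        # level(child) >= 1 + max over parents' levels, with equality by
        # definition of longest path
        for term in synth_ontology.terms.values():
            if term.obsolete or not term.parents:
                continue
            assert go_level(synth_ontology, term.id) == 1 + max(
                go_level(synth_ontology, p) for p in term.parents
            )

    def test_matches_networkx_longest_path_oracle(self, synth_ontology):
        graph = nx.DiGraph()
        for term in synth_ontology.terms.values():
            if term.obsolete:
                continue
            graph.add_node(term.id)
            for parent in term.parents:
                graph.add_edge(parent, term.id)
        order = list(nx.topological_sort(graph))
        longest = {n: 0 for n in order}
        for node in order:
            for succ in graph.successors(node):
                longest[succ] = max(longest[succ], longest[node] + 1)
        roots = set(synth_ontology.roots.values())
        for node, expected in longest.items():
            if node in roots:
                continue
            assert go_level(synth_ontology, node) == expected


class TestSurfaceForms:
    def test_name_first_then_synonyms(self, tiny_ontology):
        forms = surface_forms(tiny_ontology, "GO:0000002")
        assert forms[0] == "catalytic activity"
        assert "enzyme activity" in forms

    def test_normalization_dedup(self, tiny_ontology):
        # "Catalytic  Activity" collapses onto the name
        forms = surface_forms(tiny_ontology, "GO:0000002")
        assert len(forms) == 2

    def test_obsolete_errors(self, mixed_ontology):
        with pytest.raises(OntologyError):
            surface_forms(mixed_ontology, "GO:0000013")


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Catalytic  Activity", "catalytic activity"),
            ("serine/threonine kinase", "serine/threonine kinase"),
            ("beta-galactosidase, complex!", "beta-galactosidase complex"),
        ],
    )
    def test_rules(self, raw, expected):
        assert normalize(raw) == expected


class TestNamespaceTerms:
    def test_counts_per_namespace(self, mixed_ontology):
        assert len(namespace_terms(mixed_ontology, "molecular_function")) == 5
        # root + membrane + nucleus; the obsolete term is excluded
        assert len(namespace_terms(mixed_ontology, "cellular_component")) == 3

    def test_partition_of_live_terms(self, synth_ontology):
        sets = [namespace_terms(synth_ontology, ns) for ns in NAMESPACES]
        union = set().union(*sets)
        live = {
            t.id for t in synth_ontology.terms.values() if not t.obsolete
        }
        assert union == live
        assert sum(len(s) for s in sets) == len(union)  # pairwise disjoint

    def test_unknown_namespace_errors(self, mixed_ontology):
        with pytest.raises(OntologyError):
            namespace_terms(mixed_ontology, "molecular_funktion")


class TestRoundTrip:
    def test_write_parse_identity(self, synth_ontology):
        buffer = io.StringIO()
        write_obo(synth_ontology, buffer)
        buffer.seek(0)
        reparsed = parse_obo(buffer)
        assert set(reparsed.terms) == set(synth_ontology.terms)
        for term_id, term in synth_ontology.terms.items():
            other = reparsed.terms[term_id]
            assert other.name == term.name
            assert other.parents == term.parents
            assert other.synonyms == term.synonyms
            assert other.alt_ids == term.alt_ids
            assert other.obsolete == term.obsolete

    def test_round_trip_with_obsolete_terms(self):
        config = SynthConfig(seed=5, n_terms=6, obsolete_per_namespace=2)
        ontology = make_ontology(config)
        buffer = io.StringIO()
        write_obo(ontology, buffer)
        buffer.seek(0)
        reparsed = parse_obo(buffer)
        assert set(reparsed.terms) == set(ontology.terms)
        obsolete = [t for t in reparsed.terms.values() if t.obsolete]
        assert len(obsolete) == 6

    def test_obonet_cross_check(self, synth_ontology, tmp_path):
        """Independent OBO reader agrees on terms, edges and synonyms."""
        path = tmp_path / "synthetic.obo"
        with path.open("w") as fh:
            write_obo(synth_ontology, fh)
        graph = obonet.read_obo(str(path), ignore_obsolete=False)
        live_and_obsolete = set(synth_ontology.terms)
        assert set(graph.nodes) == live_and_obsolete
        for term_id, data in graph.nodes(data=True):
            term = synth_ontology.terms[term_id]
            assert data["name"] == term.name
            assert data["namespace"] == term.namespace
            assert tuple(sorted(data.get("is_a", ()))) == tuple(
                sorted(term.parents)
            )
            got_synonyms = {
                s.split('"')[1] for s in data.get("synonym", ())
            }
            assert got_synonyms == set(term.synonyms)
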