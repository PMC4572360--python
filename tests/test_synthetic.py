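import io

from goqa.corpus_io import read_gaf
from goqa.knn_classifier import build_kb_index, classify_knn
from goqa.ontology import normalize, parse_obo, write_obo
from goqa.corpus_io import build_micro_benchmark, write_benchmark, write_gaf
from goqa.evaluation import recall_at
from goqa.synthetic import (
    SynthConfig,
    make_corpus,
    make_ontology,
    make_qa_benchmark,
)


def obo_bytes(ontology):
    buffer = io.StringIO()
    write_obo(ontology, buffer)
    return buffer.getvalue()


class TestMakeOntology:
    def test_same_seed_identical(self):
        a = make_ontology(SynthConfig(seed=9))
        b = make_ontology(SynthConfig(seed=9))
        assert obo_bytes(a) == obo_bytes(b)

    def test_different_seed_differs(self):
        a = make_ontology(SynthConfig(seed=9))
        b = make_ontology(SynthConfig(seed=10))
        assert obo_bytes(a) != obo_bytes(b)

    def test_term_count_arithmetic(self):
        # 50 terms per namespace plus one root each -> 153
        ontology = make_ontology(SynthConfig(seed=0, n_terms=50))
        assert len(ontology) == 153

    def test_round_trip_through_parser(self, synth_ontology):
        reparsed = parse_obo(io.StringIO(obo_bytes(synth_ontology)))
        assert set(reparsed.terms) == set(synth_ontology.terms)

    def test_names_are_multiword_with_synonyms(self, synth_ontology):
        roots = set(synth_ontology.roots.values())
        for term in synth_ontology.terms.values():
            if term.id in roots:
                continue
            assert len(term.name.split()) >= 2
            if not term.obsolete:
                assert len(term.synonyms) == 2


class TestMakeCorpus:
    def test_rho_one_names_literally_present(self):
        config = SynthConfig(seed=4, rho=1.0, n_terms=6, docs_per_term=4)
        ontology = make_ontology(config)
        corpus, kb = make_corpus(config, ontology)
        for pmid, gold in kb.annotations.items():
            text = normalize(corpus[pmid].full_text)
            for go_id in gold:
                assert normalize(ontology.terms[go_id].name) in text

    def test_rho_zero_names_absent(self):
        config = SynthConfig(seed=4, rho=0.0, n_terms=6, docs_per_term=4)
        ontology = make_ontology(config)
        corpus, kb = make_corpus(config, ontology)
        for pmid, gold in kb.annotations.items():
            text = normalize(corpus[pmid].full_text)
            for go_id in gold:
                assert normalize(ontology.terms[go_id].name) not in text

    def test_every_term_has_enough_training_docs(self, synth_config,
                                                 synth_ontology, synth_corpus_kb):
        _, kb = synth_corpus_kb
        support = {}
        for gold in kb.annotations.values():
            for go_id in gold:
                support[go_id] = support.get(go_id, 0) + 1
        roots = set(synth_ontology.roots.values())
        annotatable = {
            t.id for t in synth_ontology.terms.values()
            if not t.obsolete and t.id not in roots
        }
        assert set(support) == annotatable
        assert min(support.values()) >= synth_config.docs_per_term

    def test_annotation_sizes_in_range(self, synth_corpus_kb):
        _, kb = synth_corpus_kb
        sizes = [len(g) for g in kb.annotations.values()]
        assert min(sizes) >= 1 and max(sizes) <= 4

    def test_gaf_round_trip(self, synth_ontology, synth_corpus_kb):
        _, kb = synth_corpus_kb
        buffer = io.StringIO()
        write_gaf(kb, buffer)
        buffer.seek(0)
        assert read_gaf(buffer, synth_ontology).annotations == kb.annotations


class TestMakeQaBenchmark:
    def test_seed_reproducible_tsv(self, synth_config, synth_ontology,
                                   synth_corpus_kb):
        corpus, _ = synth_corpus_kb
        outputs = []
        for _ in range(2):
            benchmark, _ = make_qa_benchmark(
                synth_config, synth_ontology, corpus
            )
            buffer = io.StringIO()
            write_benchmark(benchmark, buffer)
            outputs.append(buffer.getvalue())
        assert outputs[0] == outputs[1]

    def test_entity_token_counts(self, synth_config, synth_ontology,
                                 synth_corpus_kb):
        corpus, _ = synth_corpus_kb
        benchmark, extended = make_qa_benchmark(
            synth_config, synth_ontology, corpus
        )
        for entry in benchmark.entries:
            token = entry.entity.lower()
            containing = [
                p for p, d in extended.items()
                if token in normalize(d.full_text).split()
            ]
            assert len(containing) == synth_config.docs_per_entity

    def test_gold_sets_sized_and_in_namespace(self, synth_config,
                                              synth_ontology, synth_corpus_kb):
        corpus, _ = synth_corpus_kb
        benchmark, _ = make_qa_benchmark(synth_config, synth_ontology, corpus)
        lo, hi = synth_config.gold_per_question
        for entry in benchmark.entries:
            assert lo <= len(entry.gold) <= hi
            for go_id in entry.gold:
                assert synth_ontology.terms[go_id].namespace == entry.namespace

    def test_entity_documents_are_not_annotated(self, synth_config,
                                                synth_ontology, synth_corpus_kb):
        corpus, kb = synth_corpus_kb
        _, extended = make_qa_benchmark(synth_config, synth_ontology, corpus)
        new_pmids = set(extended) - set(corpus)
        assert new_pmids and not (new_pmids & set(kb.annotations))


class TestClassifierRegimes:
    """The generator's rho dial separates the two classifier families."""

    def test_dictionary_blind_when_nothing_is_literal(self):
        # rho=0: term names never occur in text and topic tokens share no
        # vocabulary with names, so the dictionary classifier finds nothing
        from goqa.experiments import micro_reading_eval

        config = SynthConfig(seed=3, rho=0.0, n_terms=10, docs_per_term=10)
        ontology = make_ontology(config)
        corpus, kb = make_corpus(config, ontology)
        _, recall = micro_reading_eval(ontology, corpus, kb, "dict", n=60, seed=3)
        assert recall == 0.0

    def test_knn_recovers_implicit_annotations(self):
        # rho=0 with >=10 training abstracts per term: supervised
        # micro-reading still reaches Recall@5 >= 0.7
        from goqa.experiments import micro_reading_eval

        config = SynthConfig(seed=3, rho=0.0)
        ontology = make_ontology(config)
        corpus, kb = make_corpus(config, ontology)
        _, recall = micro_reading_eval(ontology, corpus, kb, "knn", n=100, seed=3)
        assert recall >= 0.7


class TestTrainingSupportStratification:
    def test_recall_degrades_with_sparse_training(self):
        """k-NN recovers well-supported terms better than terms with under
        10 training abstracts (support is thinned artificially)."""
        config = SynthConfig(seed=6, rho=0.0, n_terms=12, docs_per_term=12)
        ontology = make_ontology(config)
        corpus, kb = make_corpus(config, ontology)
        # thin half the terms to 3 primary training docs
        roots = set(ontology.roots.values())
        terms = sorted(
            t.id for t in ontology.terms.values()
            if not t.obsolete and t.id not in roots
        )
        sparse = set(terms[::2])
        kept = {}
        seen_count = {}
        for pmid in sorted(kb.annotations, key=int):
            gold = kb.annotations[pmid]
            keep = set()
            for go_id in sorted(gold):
                seen_count[go_id] = seen_count.get(go_id, 0) + 1
                if go_id not in sparse or seen_count[go_id] <= 3:
                    keep.add(go_id)
            if keep:
                kept[pmid] = keep
        thinned = type(kb)()
        for pmid, gold in kept.items():
            for go_id in gold:
                thinned.add(pmid, go_id)
        kb_index = build_kb_index(thinned, corpus, k=50)
        per_stratum = {True: [], False: []}
        benchmark = build_micro_benchmark(thinned, corpus, 150, seed=2)
        for doc, gold in benchmark:
            predicted = [
                st.go_id
                for st in classify_knn(
                    kb_index, doc.full_text, m=5, exclude_pmids=[doc.pmid]
                )
            ]
            for go_id in gold:
                hit = float(go_id in predicted[:5])
                per_stratum[go_id in sparse].append(hit)
        dense_recall = sum(per_stratum[False]) / len(per_stratum[False])
        sparse_recall = sum(per_stratum[True]) / len(per_stratum[True])
        assert dense_recall > sparse_recall
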