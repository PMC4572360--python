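"""Reproducible experiment drivers over synthetic worlds.

Thin orchestration used by the test harness, the CLI and the acceptance
script: build a synthetic world (ontology + curated corpus + QA benchmark),
run the QA pipeline with a chosen classifier and retrieval mode, and score
it; plus a micro-reading evaluator that classifies single abstracts under
the leave-out protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import Benchmark, Document, KnowledgeBase, build_micro_benchmark
from .dict_classifier import build_term_index, classify_dictionary
from .evaluation import EvalReport, answer_sets_to_rankings, evaluate, recall_at, top_precision
from .knn_classifier import build_kb_index, classify_knn
from .ontology import NAMESPACES, Ontology
from .qa_pipeline import DictionaryClassifier, KNNClassifier, answer
from .retrieval import Index, RetrievalParams, build_index
from .synthetic import SynthConfig, make_corpus, make_ontology, make_qa_benchmark

__all__ = ["SynthWorld", "build_world", "run_qa_pipeline", "micro_reading_eval"]


@dataclass
class SynthWorld:
    """Everything a pipeline run needs, generated from one config."""

    config: SynthConfig
    ontology: Ontology
    corpus: dict[str, Document]       # curated (annotated) documents only
    kb: KnowledgeBase
    benchmark: Benchmark
    extended: dict[str, Document]     # curated + entity documents
    index: Index                      # over the extended corpus


def build_world(config: SynthConfig) -> SynthWorld:
    ontology = make_ontology(config)
    corpus, kb = make_corpus(config, ontology)
    benchmark, extended = make_qa_benchmark(config, ontology, corpus)
    index = build_index(
        {p: d.full_text for p, d in extended.items()},
        dates={p: d.date for p, d in extended.items() if d.date is not None},
    )
    return SynthWorld(
        config=config,
        ontology=ontology,
        corpus=corpus,
        kb=kb,
        benchmark=benchmark,
        extended=extended,
        index=index,
    )


def run_qa_pipeline(
    world: SynthWorld,
    classifier: str = "knn",
    mode: str = "bm25",
    k: int = 100,
    m: int = 5,
    r: int = 5,
) -> EvalReport:
    """Answer every benchmark question and score the answer sets."""
    if classifier == "dict":
        clf = DictionaryClassifier(world.ontology)
    elif classifier == "knn":
        kb_index = build_kb_index(world.kb, world.extended, k=k)
        clf = KNNClassifier(kb_index, world.ontology, k=k)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    params = RetrievalParams(mode=mode)
    answer_sets = [
        answer(
            entry.question, world.index, world.extended, clf,
            world.ontology, params, m=m,
        )
        for entry in world.benchmark.entries
    ]
    return evaluate(
        world.benchmark, answer_sets_to_rankings(answer_sets), r,
        world.ontology,
    )


def micro_reading_eval(
    ontology: Ontology,
    corpus: dict[str, Document],
    kb: KnowledgeBase,
    classifier: str,
    n: int,
    seed: int,
    m: int = 5,
    r: int = 5,
    k: int = 100,
) -> tuple[float, float]:
    """(mean P0, mean recall@r) over n sampled annotated abstracts.

    The k-NN classifier runs under leave-out: each abstract's own pmid is
    excluded from its neighbourhood.
    """
    sample = build_micro_benchmark(kb, corpus, n, seed)
    if classifier == "dict":
        term_index = build_term_index(ontology, NAMESPACES)

        def predict(doc):
            return [st.go_id for st in classify_dictionary(term_index, doc.full_text, m)]

    elif classifier == "knn":
        kb_index = build_kb_index(kb, corpus, k=k)

        def predict(doc):
            return [
                st.go_id
                for st in classify_knn(
                    kb_index, doc.full_text, k=k, m=m, exclude_pmids=[doc.pmid]
                )
            ]

    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    p0s, recalls = [], []
    for doc, gold in sample:
        predicted = predict(doc)
        p0s.append(top_precision(predicted, gold))
        recalls.append(recall_at(predicted, gold, r))
    return float(np.mean(p0s)), float(np.mean(recalls))
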