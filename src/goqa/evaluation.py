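"""Ranked-answer evaluation: Top Precision, Recall at rank, macro
averaging, strict-ID matching, and a paired significance test.

Top Precision (P0) is the interpolated precision at recall 0 — the best
precision observed at any rank of the answer list. Recall@r is the
fraction of gold answers present in the top r. Matching is strict: a
system must output the exact GO identifier (after alt-id resolution); no
hierarchical or semantic-similarity credit is given, so returning a gold
term's child counts as wrong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Collection, Mapping, Sequence

import numpy as np

from .corpus_io import Benchmark
from .ontology import Ontology, resolve_id
from .qa_pipeline import AnswerSet

__all__ = [
    "QuestionScore",
    "EvalReport",
    "top_precision",
    "recall_at",
    "evaluate",
    "answer_sets_to_rankings",
    "paired_randomization_test",
]


@dataclass(frozen=True)
class QuestionScore:
    question: str
    p0: float
    recall_at_r: float


@dataclass
class EvalReport:
    per_question: list[QuestionScore]
    macro_p0: float
    macro_recall: float
    r: int
    significance: tuple[str, float] | None = None

    def summary(self) -> str:
        lines = [
            f"questions evaluated: {len(self.per_question)}",
            f"macro P0:           {self.macro_p0:.3f}",
            f"macro recall@{self.r}:    {self.macro_recall:.3f}",
        ]
        if self.significance is not None:
            label, p_value = self.significance
            lines.append(f"significance ({label}): p = {p_value:.4f}")
        return "\n".join(lines)

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write(f"question\tP0\trecall_at_{self.r}\n")
        for qs in self.per_question:
            stream.write(f"{qs.question}\t{qs.p0:.4f}\t{qs.recall_at_r:.4f}\n")
        stream.write(
            f"MACRO\t{self.macro_p0:.4f}\t{self.macro_recall:.4f}\n"
        )


def top_precision(ranked: Sequence[str], gold: Collection[str]) -> float:
    """max over ranks i of |top-i ∩ gold| / i; 0 if nothing relevant.

    An empty answer list scores 0 by definition.
    """
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list contains duplicate ids")
    gold = set(gold)
    best = 0.0
    hits = 0
    for i, go_id in enumerate(ranked, start=1):
        if go_id in gold:
            hits += 1
            best = max(best, hits / i)
    return best


def recall_at(ranked: Sequence[str], gold: Collection[str], r: int) -> float:
    """|top-r ∩ gold| / |gold|."""
    if r < 1:
        raise ValueError("r must be >= 1")
    gold = set(gold)
    if not gold:
        raise ValueError("gold set is empty")
    return len(set(ranked[:r]) & gold) / len(gold)


def answer_sets_to_rankings(
    answer_sets: Sequence[AnswerSet],
) -> dict[str, list[str]]:
    """Key answer sets by raw question text for :func:`evaluate`."""
    return {a.question.raw: a.ranked_ids for a in answer_sets}


def evaluate(
    benchmark: Benchmark,
    answers: Mapping[str, Sequence[str]],
    r: int,
    ontology: Ontology,
) -> EvalReport:
    """Score ranked answers against a benchmark, strict-ID matching.

    ``answers`` maps question text to a ranked GO id list. A benchmark
    question with no answer entry is scored as an empty list (0/0), not
    excluded, so macro averages stay comparable across systems. Answer
    keys that match no benchmark question are an error.
    """
    questions = {entry.question for entry in benchmark.entries}
    stray = set(answers) - questions
    if stray:
        raise ValueError(
            f"answers given for questions not in benchmark: {sorted(stray)[:3]}"
        )
    per_question: list[QuestionScore] = []
    for entry in benchmark.entries:
        ranked_raw = answers.get(entry.question, [])
        ranked = [resolve_id(ontology, g) for g in ranked_raw]
        if len(set(ranked)) != len(ranked):
            raise ValueError(
                f"duplicate ids after alt-id resolution for {entry.question!r}"
            )
        gold = {resolve_id(ontology, g) for g in entry.gold}
        per_question.append(
            QuestionScore(
                question=entry.question,
                p0=top_precision(ranked, gold),
                recall_at_r=recall_at(ranked, gold, r),
            )
        )
    macro_p0 = float(np.mean([q.p0 for q in per_question])) if per_question else 0.0
    macro_recall = (
        float(np.mean([q.recall_at_r for q in per_question])) if per_question else 0.0
    )
    return EvalReport(
        per_question=per_question,
        macro_p0=macro_p0,
        macro_recall=macro_recall,
        r=r,
    )


def paired_randomization_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_permutations: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided sign-flip randomization test on paired per-question scores.

    Under the null that the two systems are exchangeable per question, the
    sign of each paired difference is random; p = (1 + #{permuted |mean
    diff| >= observed}) / (1 + n_permutations).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    diffs = a - b
    observed = abs(diffs.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, diffs.size))
    permuted = np.abs((signs * diffs).mean(axis=1))
    exceed = int(np.sum(permuted >= observed - 1e-12))
    return (1 + exceed) / (1 + n_permutations)
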