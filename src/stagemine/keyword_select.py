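"""Greedy max-relevance / min-redundancy keyword selection per stage.

For stage i with description documents A_i, a candidate keyword's relevance
is the cosine similarity between its per-document occurrence-count vector
and the vector of per-document total word counts; its redundancy against an
already-selected keyword is the cosine of their count vectors.  Keywords are
chosen one at a time, the k-th maximizing

    relevance(w) - (1/(k-1)) * sum of redundancy(w, selected)

over the remaining candidates (the first keyword maximizes relevance alone).
Keywords selected by exactly one stage become the labeled keywords that seed
the factorization's G0 matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import StageDescriptions
from .textprep import stem_tokens

__all__ = [
    "StageVocabulary",
    "KeywordSet",
    "cosine_similarity",
    "stage_relevance",
    "keyword_similarity",
    "mrmr_select",
    "build_keyword_labels",
    "select_keywords",
]


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Standard cosine: dot product over the product of Euclidean norms."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same dimension")
    nu = math.sqrt(float(u @ u))
    nv = math.sqrt(float(v @ v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(u @ v) / (nu * nv)


@dataclass
class StageVocabulary:
    """Stemmed vocabulary and per-document counts of one stage's descriptions.

    ``counts[w]`` is the m-vector of occurrences of stem ``w`` in each of the
    stage's m description documents; ``totals`` the m-vector of per-document
    total stem counts.
    """

    stage_id: int
    stems: set[str]
    counts: dict[str, np.ndarray]
    totals: np.ndarray

    @classmethod
    def from_documents(cls, stage_id: int, documents: Sequence[str]) -> "StageVocabulary":
        docs = [stem_tokens(d) for d in documents]
        if not docs:
            raise ValueError("a stage needs at least one description document")
        stems = sorted({s for doc in docs for s in doc})
        counts = {w: np.zeros(len(docs)) for w in stems}
        totals = np.zeros(len(docs))
        for j, doc in enumerate(docs):
            totals[j] = len(doc)
            for s in doc:
                counts[s][j] += 1.0
        return cls(stage_id=stage_id, stems=set(stems), counts=counts, totals=totals)

    @property
    def n_documents(self) -> int:
        return len(self.totals)


def stage_relevance(word: str, vocab: StageVocabulary) -> float:
    """Cosine between the word's per-document counts and document lengths.

    A word occurring in no document of the stage has relevance 0 by
    convention.
    """
    counts = vocab.counts.get(word)
    if counts is None or not counts.any():
        return 0.0
    return cosine_similarity(counts, vocab.totals)


def keyword_similarity(wq: str, wp: str, vocab: StageVocabulary) -> float:
    """Cosine of the two keywords' per-document count vectors (0 if absent)."""
    cq = vocab.counts.get(wq)
    cp = vocab.counts.get(wp)
    if cq is None or cp is None or not cq.any() or not cp.any():
        return 0.0
    return cosine_similarity(cq, cp)


def mrmr_select(vocab: StageVocabulary, n_keywords: int) -> list[str]:
    """Select up to ``n_keywords`` stems greedily by relevance minus redundancy.

    Step k maximizes ``relevance(w) - (1/(k-1)) * sum(sim(w, selected))``;
    for k=1 the redundancy term is 0.  Ties break to the lexicographically
    smallest stem.  Stops early when the vocabulary is exhausted.
    """
    if n_keywords < 1:
        raise ValueError("n_keywords must be >= 1")
    candidates = sorted(vocab.stems)
    relevance = {w: stage_relevance(w, vocab) for w in candidates}
    selected: list[str] = []
    while len(selected) < n_keywords and len(selected) < len(vocab.stems):
        k = len(selected) + 1
        best_word = None
        best_score = -math.inf
        for w in candidates:
            if w in selected:
                continue
            score = relevance[w]
            if k > 1:
                score -= sum(keyword_similarity(w, p, vocab) for p in selected) / (k - 1)
            if score > best_score:
                best_score = score
                best_word = w
        assert best_word is not None
        selected.append(best_word)
    return selected


@dataclass
class KeywordSet:
    """Ordered union of per-stage selections with provenance.

    ``unique_stage[w]`` is the stage id for keywords selected by exactly one
    stage (these become labeled keywords), else ``None``.
    """

    keywords: list[str]
    provenance: dict[str, list[int]]
    unique_stage: dict[str, int | None] = field(init=False)

    def __post_init__(self) -> None:
        for w in self.keywords:
            if not self.provenance.get(w):
                raise ValueError(f"keyword {w!r} has empty provenance")
        self.unique_stage = {
            w: (stages[0] if len(stages) == 1 else None)
            for w, stages in self.provenance.items()
        }

    def __len__(self) -> int:
        return len(self.keywords)

    @property
    def labeled_fraction(self) -> float:
        if not self.keywords:
            return 0.0
        n = sum(1 for w in self.keywords if self.unique_stage[w] is not None)
        return n / len(self.keywords)

    def keyword_stages(self) -> list[int | None]:
        """Per-keyword labeled stage (None for multi-stage keywords)."""
        return [self.unique_stage[w] for w in self.keywords]


def build_keyword_labels(selections: Mapping[int, Sequence[str]]) -> KeywordSet:
    """Merge per-stage ordered selections into one keyword set.

    The union is stage-major in selection order; a keyword selected by more
    than one stage appears once, at its first position, with multi-stage
    provenance and no unique stage label.
    """
    keywords: list[str] = []
    provenance: dict[str, list[int]] = {}
    for stage in sorted(selections):
        if not selections[stage]:
            raise ValueError(f"stage {stage} selected no keywords")
        for w in selections[stage]:
            if w not in provenance:
                provenance[w] = []
                keywords.append(w)
            if stage not in provenance[w]:
                provenance[w].append(stage)
    return KeywordSet(keywords=keywords, provenance=provenance)


def select_keywords(
    descriptions: StageDescriptions,
    n_total: int = 20,
    per_stage: int | None = None,
) -> KeywordSet:
    """Run mRMR selection for every stage and merge the results.

    The total keyword budget ``n_total`` is split evenly across stages
    (rounded up), unless an explicit ``per_stage`` budget is given.  20 total
    keywords is the default operating point.
    """
    S = descriptions.n_stages
    budget = per_stage if per_stage is not None else -(-n_total // S)
    selections = {
        stage: mrmr_select(
            StageVocabulary.from_documents(stage, descriptions.sentences[stage]),
            budget,
        )
        for stage in range(1, S + 1)
    }
    return build_keyword_labels(selections)
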