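"""End-to-end classification pipeline over a corpus and stage descriptions.

Chains the method's steps: mRMR keyword selection from the stage
descriptions, document-term matrix construction, assembly of the partial
label constraints (expert note labels plus uniquely-selected keywords, and
optionally the description sentences themselves appended as labeled rows),
the semi-supervised factorization, and category classification of every
note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import Corpus, StageDescriptions
from .keyword_select import KeywordSet, select_keywords
from .seminmf import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    FactorizationResult,
    LabelConstraints,
    fit_semi_nmf,
)
from .staging import classify_notes
from .textprep import DocTermMatrix, build_doc_term_matrix

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run, aligned with the input corpus."""

    keyword_set: KeywordSet
    matrix: DocTermMatrix
    constraints: LabelConstraints
    factorization: FactorizationResult
    note_probabilities: np.ndarray  # (n_notes, n_categories)
    note_categories: list[int]
    collapse_at: int | None


def run_pipeline(
    corpus: Corpus,
    descriptions: StageDescriptions,
    n_keywords: int = 20,
    per_stage: int | None = None,
    collapse_at: int | None = 4,
    alpha: float = 1.0,
    beta: float = 1.0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    include_descriptions: bool = True,
    keyword_set: KeywordSet | None = None,
) -> PipelineResult:
    """Classify every note of ``corpus`` into stage categories.

    ``include_descriptions`` appends the stage-description sentences to the
    document-term matrix as additional rows labeled with their stage, so the
    descriptions act as labeled data alongside expert-labeled notes.
    ``keyword_set`` bypasses reselection when given.
    """
    if keyword_set is None:
        keyword_set = select_keywords(
            descriptions, n_total=n_keywords, per_stage=per_stage
        )
    documents = [note.text for note in corpus.notes]
    doc_labels: list[int | None] = [note.label for note in corpus.notes]
    if include_descriptions:
        for stage in range(1, descriptions.n_stages + 1):
            for sentence in descriptions.sentences[stage]:
                documents.append(sentence)
                doc_labels.append(stage)
    matrix = build_doc_term_matrix(documents, keyword_set.keywords)
    constraints = LabelConstraints.from_labels(
        doc_labels,
        keyword_set.keyword_stages(),
        n_stages=corpus.n_stages,
        alpha=alpha,
        beta=beta,
    )
    factorization = fit_semi_nmf(
        matrix.X, constraints, max_iter=max_iter, tol=tol, seed=seed
    )
    probs, categories = classify_notes(factorization, corpus, collapse_at)
    return PipelineResult(
        keyword_set=keyword_set,
        matrix=matrix,
        constraints=constraints,
        factorization=factorization,
        note_probabilities=probs,
        note_categories=categories,
        collapse_at=collapse_at,
    )
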