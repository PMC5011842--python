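"""From stage probabilities to stage calls, intervals, and transition models.

The factorization assigns every log note a probability vector over stages;
this module pools stages into categories (by default stages >= 4 become one
"4 or later" category), takes argmax stage calls, evaluates them against
expert labels, detects per-site stage start/end dates from sustained runs of
high stage probability, flags whether a site ever attained a given stage,
and estimates maximum-likelihood Markov transition matrices over consecutive
note categories.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import Corpus
from .seminmf import FactorizationResult

__all__ = [
    "StageTrajectory",
    "EvaluationReport",
    "TransitionModel",
    "collapse_probabilities",
    "classify_notes",
    "build_trajectories",
    "evaluate_predictions",
    "detect_stage_interval",
    "flag_stage_attainment",
    "estimate_transition_matrix",
    "baseline_classifier",
]


def collapse_probabilities(
    probs: np.ndarray, collapse_at: int | None
) -> np.ndarray:
    """Pool stage probabilities into categories by summation."""
    probs = np.asarray(probs, dtype=float)
    S = probs.shape[1]
    if collapse_at is None or collapse_at >= S:
        return probs
    head = probs[:, : collapse_at - 1]
    tail = probs[:, collapse_at - 1 :].sum(axis=1, keepdims=True)
    return np.hstack([head, tail])


def _argmax_categories(probs: np.ndarray) -> list[int]:
    # np.argmax already returns the lowest index on ties
    return [int(j) + 1 for j in np.argmax(probs, axis=1)]


def classify_notes(
    result: FactorizationResult,
    corpus: Corpus,
    collapse_at: int | None = 4,
) -> tuple[np.ndarray, list[int]]:
    """Per-note category probability vectors and argmax category calls.

    Rows of ``result.F`` must align with ``corpus.notes`` (notes first when
    description sentences were appended to the matrix).  Ties in the argmax
    break to the lowest category.
    """
    if result.F.shape[0] < len(corpus.notes):
        raise ValueError(
            f"factorization has {result.F.shape[0]} rows for "
            f"{len(corpus.notes)} notes"
        )
    probs = collapse_probabilities(result.F[: len(corpus.notes)], collapse_at)
    return probs, _argmax_categories(probs)


@dataclass
class StageTrajectory:
    """Date-ordered per-site sequence of category-probability vectors."""

    site_id: str
    dates: list[dt.date]
    probabilities: np.ndarray  # (n_notes, n_categories)
    categories: list[int]

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("trajectory dates must be non-decreasing")

    def __len__(self) -> int:
        return len(self.dates)


def build_trajectories(
    corpus: Corpus, probabilities: np.ndarray, categories: Sequence[int]
) -> dict[str, StageTrajectory]:
    """Group aligned per-note probabilities into per-site trajectories."""
    probabilities = np.asarray(probabilities, dtype=float)
    if len(probabilities) != len(corpus.notes) or len(categories) != len(corpus.notes):
        raise ValueError("probabilities/categories must align with corpus notes")
    out: dict[str, StageTrajectory] = {}
    index: dict[str, list[int]] = {}
    for i, note in enumerate(corpus.notes):
        index.setdefault(note.site_id, []).append(i)
    for site, idx in index.items():
        out[site] = StageTrajectory(
            site_id=site,
            dates=[corpus.notes[i].date for i in idx],
            probabilities=probabilities[idx],
            categories=[categories[i] for i in idx],
        )
    return out


@dataclass
class EvaluationReport:
    """Accuracy plus a true-by-predicted confusion count matrix."""

    accuracy: float
    confusion: np.ndarray
    n: int
    labels: list[int]


def evaluate_predictions(
    predicted: Sequence[int], truth: Sequence[int], n_categories: int | None = None
) -> EvaluationReport:
    """Proportion of correct calls and the confusion matrix (rows = truth)."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    if len(truth) == 0:
        raise ValueError("nothing to evaluate")
    if n_categories is None:
        n_categories = max(max(predicted), max(truth))
    labels = list(range(1, n_categories + 1))
    confusion = np.zeros((n_categories, n_categories), dtype=int)
    for p, t in zip(predicted, truth):
        confusion[t - 1, p - 1] += 1
    n = len(truth)
    return EvaluationReport(
        accuracy=float(np.trace(confusion)) / n,
        confusion=confusion,
        n=n,
        labels=labels,
    )


def detect_stage_interval(
    trajectory: StageTrajectory,
    stage: int,
    threshold: float = 0.5,
    min_run: int = 2,
    smooth_window: int | None = None,
) -> list[tuple[dt.date, dt.date]]:
    """Start/end dates of runs of sustained high probability for a stage.

    An interval opens at the first note of a run of at least ``min_run``
    consecutive notes with ``p_stage >= threshold`` and closes at the last
    note of that run; disjoint runs yield multiple intervals (re-entry).
    ``smooth_window`` optionally applies a centered moving average to the
    probability series first.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    p = trajectory.probabilities[:, stage - 1]
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        p = np.convolve(p, kernel, mode="same")
    above = p >= threshold
    intervals: list[tuple[dt.date, dt.date]] = []
    start: int | None = None
    for i, hit in enumerate(above):
        if hit and start is None:
            start = i
        elif not hit and start is not None:
            if i - start >= min_run:
                intervals.append((trajectory.dates[start], trajectory.dates[i - 1]))
            start = None
    if start is not None and len(above) - start >= min_run:
        intervals.append((trajectory.dates[start], trajectory.dates[-1]))
    return intervals


def flag_stage_attainment(
    site_categories: Mapping[str, Sequence[int]],
    stage: int,
    subset: Iterable[str] | None = None,
) -> tuple[dict[str, bool], float]:
    """Flag sites with any note called at or beyond ``stage``.

    Returns per-site flags and the flagged percentage among ``subset``
    (all sites when omitted).  Applied to sites whose ground truth never
    reached the stage, the rate is a false-flag (over-projection) rate.
    """
    if not site_categories:
        raise ValueError("no sites given")
    flags = {
        site: any(c >= stage for c in cats) for site, cats in site_categories.items()
    }
    members = list(subset) if subset is not None else list(site_categories)
    if not members:
        raise ValueError("empty site subset")
    missing = [s for s in members if s not in flags]
    if missing:
        raise ValueError(f"sites not in corpus: {missing}")
    rate = 100.0 * sum(flags[s] for s in members) / len(members)
    return flags, rate


@dataclass
class TransitionModel:
    """Empirical Markov chain over note categories.

    ``P`` is row-stochastic wherever a row has observed transitions; rows
    never observed are all zero and listed in ``zero_rows``.
    """

    P: np.ndarray
    counts: np.ndarray
    n_transitions: int
    zero_rows: list[int] = field(default_factory=list)


def estimate_transition_matrix(
    sequences: Iterable[Sequence[int]],
    n_categories: int | None = None,
    laplace: float = 0.0,
) -> TransitionModel:
    """Maximum-likelihood transition matrix from consecutive note pairs.

    ``counts[a-1][b-1]`` is the number of consecutive pairs (a -> b) pooled
    across sequences; ``laplace`` optionally adds that constant to every
    cell before normalizing.
    """
    seqs = [list(s) for s in sequences]
    if n_categories is None:
        n_categories = max((max(s) for s in seqs if s), default=0)
    if n_categories < 1:
        raise ValueError("no categories observed")
    counts = np.zeros((n_categories, n_categories))
    n_transitions = 0
    for seq in seqs:
        for a, b in zip(seq, seq[1:]):
            counts[a - 1, b - 1] += 1
            n_transitions += 1
    if n_transitions == 0:
        raise ValueError("all sequences are shorter than 2 notes")
    smoothed = counts + laplace
    row_sums = smoothed.sum(axis=1)
    P = np.zeros_like(smoothed)
    nonzero = row_sums > 0
    P[nonzero] = smoothed[nonzero] / row_sums[nonzero, None]
    zero_rows = [int(i) for i in np.flatnonzero(~nonzero)]
    return TransitionModel(
        P=P,
        counts=counts.astype(int),
        n_transitions=n_transitions,
        zero_rows=zero_rows,
    )


def baseline_classifier(kind: str = "svm"):
    """Standard supervised baseline for comparison runs.

    Returns an untrained scikit-learn estimator: a linear-kernel SVM or a
    multinomial naive Bayes model; train it on labeled rows of X and compare
    with the semi-supervised factorization.
    """
    if kind == "svm":
        from sklearn.svm import LinearSVC

        return LinearSVC()
    if kind in ("nb", "naive_bayes"):
        from sklearn.naive_bayes import MultinomialNB

        return MultinomialNB()
    raise ValueError(f"unknown baseline {kind!r}")
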