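"""Synthetic stage-description and log-note corpora with known ground truth.

The generator emulates the structure of a multi-site implementation trial's
communication log: each site traverses the stages in order, occupying each
for a random number of days, with a configurable fraction of sites stalling
before the final stage (the default 31/40 mirrors the shape of the
motivating trial, where most counties never progressed beyond stage 3).
Notes are bags of synthetic stems drawn from the occupied stage's
vocabulary, with a background-noise word rate; adjacent stages can share a
fraction of their vocabularies to emulate confusable stage definitions.

Words are pronounceable consonant-vowel stems constructed to be fixed points
of the Porter stemmer, so the generator exercises tokenization without
coupling the ground truth to stemmer behavior.  The default scale is roughly
one tenth of the motivating study: 4 stage categories, 40 sites, ~460 notes.
All randomness flows from ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import Corpus, LogNote, StageDescriptions
from .textprep import porter_stem

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_stage_vocabularies",
    "generate_site_trajectory",
    "generate_corpus",
    "interval_boundary_recovery",
]

_CONSONANTS = "bdfgklmnprtv"
_VOWELS = "aou"


@dataclass
class GeneratorConfig:
    """Study-shape parameters for the synthetic corpus.

    Defaults emulate the motivating trial at one-tenth scale: 4 stage
    categories, 40 sites with ~11.5 notes each (~460 notes), stage-specific
    vocabularies of 20 stems, notes of ~15 words, 10 % expert-labeled notes,
    5 % background-noise words, and 31/40 of sites stalling at stage 3.
    """

    n_stages: int = 4
    n_sites: int = 40
    mean_notes_per_site: float = 11.5
    vocab_size: int = 20
    overlap_fraction: float = 0.0
    note_length_mean: float = 15.0
    note_length_min: int = 4
    labeled_fraction: float = 0.1
    noise_rate: float = 0.05
    background_vocab_size: int = 30
    stage_duration_days_mean: int = 90
    stage_duration_days_min: int = 14
    stop_fraction: float = 31 / 40
    stop_stage: int = 3
    sentences_per_stage: int | Sequence[int] = 6
    sentence_length: int = 8
    description_core_weight: float = 4.0
    start_date: dt.date = dt.date(2006, 5, 1)
    start_jitter_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0 <= self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in [0, 1]")
        if self.n_stages < 2 or self.n_sites < 1 or self.vocab_size < 1:
            raise ValueError("sizes must be >= 1 (and n_stages >= 2)")
        if not 1 <= self.stop_stage <= self.n_stages:
            raise ValueError("stop_stage must be in 1..n_stages")

    def sentences_for_stage(self, stage: int) -> int:
        if isinstance(self.sentences_per_stage, int):
            return self.sentences_per_stage
        return self.sentences_per_stage[stage - 1]


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated corpus.

    ``note_stages`` aligns with ``Corpus.notes``; ``site_intervals`` maps a
    site to its ordered (stage, start date, end date) occupancy; the
    vocabularies are the generating per-stage word lists.
    """

    note_stages: list[int]
    site_intervals: dict[str, list[tuple[int, dt.date, dt.date]]]
    vocabularies: list[list[str]]
    background_vocabulary: list[str]
    labeled_indices: list[int] = field(default_factory=list)


def _make_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Pronounceable CV-syllable stems that the Porter stemmer leaves alone."""
    words: list[str] = []
    while len(words) < n:
        n_syll = int(rng.integers(2, 4))
        w = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        w += _CONSONANTS[rng.integers(len(_CONSONANTS))]
        if w in taken or porter_stem(w) != w:
            continue
        taken.add(w)
        words.append(w)
    return words


def generate_stage_vocabularies(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[list[str]]:
    """Per-stage word lists; adjacent stages share ``overlap_fraction`` words.

    Each adjacent pair shares ``round(overlap_fraction * vocab_size)`` words;
    with overlap 0 the vocabularies are pairwise disjoint.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    taken: set[str] = set()
    n_shared = round(config.overlap_fraction * config.vocab_size)
    shared = [
        _make_words(rng, n_shared, taken) for _ in range(config.n_stages - 1)
    ]
    vocabs: list[list[str]] = []
    for s in range(config.n_stages):
        before = shared[s - 1] if s > 0 else []
        after = shared[s] if s < config.n_stages - 1 else []
        n_core = config.vocab_size - len(before) - len(after)
        if n_core < 1:
            raise ValueError("overlap_fraction leaves no stage-specific words")
        vocabs.append(before + _make_words(rng, n_core, taken) + after)
    return vocabs


def generate_site_trajectory(
    config: GeneratorConfig, site_id: str, seed: int
) -> list[tuple[int, dt.date, dt.date]]:
    """Dated true-stage occupancy for one site, stages visited in order.

    With probability ``stop_fraction`` the site never progresses beyond
    ``stop_stage``.  Each occupied stage lasts a uniform number of days in
    ``[min, 2*mean - min]``.
    """
    rng = np.random.default_rng(seed)
    final = (
        config.stop_stage
        if rng.random() < config.stop_fraction
        else config.n_stages
    )
    start = config.start_date + dt.timedelta(
        days=int(rng.integers(0, config.start_jitter_days + 1))
    )
    lo = config.stage_duration_days_min
    hi = max(lo + 1, 2 * config.stage_duration_days_mean - lo)
    intervals: list[tuple[int, dt.date, dt.date]] = []
    cursor = start
    for stage in range(1, final + 1):
        days = int(rng.integers(lo, hi + 1))
        end = cursor + dt.timedelta(days=days - 1)
        intervals.append((stage, cursor, end))
        cursor = end + dt.timedelta(days=1)
    return intervals


def _sample_note_text(
    rng: np.random.Generator,
    vocab: Sequence[str],
    background: Sequence[str],
    config: GeneratorConfig,
) -> str:
    length = max(config.note_length_min, int(rng.poisson(config.note_length_mean)))
    words = []
    for _ in range(length):
        if background and rng.random() < config.noise_rate:
            words.append(background[rng.integers(len(background))])
        else:
            words.append(vocab[rng.integers(len(vocab))])
    return " ".join(words)


def _sample_date_in(
    rng: np.random.Generator, start: dt.date, end: dt.date
) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate_corpus(
    config: GeneratorConfig,
    category_counts: Sequence[int] | None = None,
    labeled_counts: Sequence[int] | None = None,
) -> tuple[Corpus, StageDescriptions, SyntheticTruth]:
    """Generate a corpus, its stage descriptions, and the generating truth.

    By default each site receives a Poisson number of notes at uniform dates
    within its occupancy, so per-stage counts follow the (imbalanced)
    occupancy pattern.  ``category_counts`` pins the number of *unlabeled*
    notes per stage instead (e.g. a reference data-distribution shape), and
    ``labeled_counts`` pins the number of expert-labeled notes per stage;
    pinning a stage no site ever occupies is an error.
    """
    master = np.random.default_rng(config.seed)
    # independent child seeds, drawn in a fixed order
    seeds = master.integers(0, 2**31 - 1, size=6 + config.n_sites)
    vocabs = generate_stage_vocabularies(
        config, np.random.default_rng(int(seeds[0]))
    )
    taken = {w for v in vocabs for w in v}
    background = _make_words(
        np.random.default_rng(int(seeds[1])), config.background_vocab_size, taken
    )

    # stage descriptions emphasize the stage's own core milestone words;
    # words shared with neighboring stages appear too, but down-weighted by
    # description_core_weight, so confusable definitions grow with overlap
    n_shared = round(config.overlap_fraction * config.vocab_size)
    desc_rng = np.random.default_rng(int(seeds[2]))
    sentences: dict[int, list[str]] = {}
    for stage in range(1, config.n_stages + 1):
        before = n_shared if stage > 1 else 0
        after = n_shared if stage < config.n_stages else 0
        full = vocabs[stage - 1]
        weights = np.ones(len(full))
        weights[before : len(full) - after] = config.description_core_weight
        p = weights / weights.sum()
        sentences[stage] = [
            " ".join(
                full[i]
                for i in desc_rng.choice(len(full), size=config.sentence_length, p=p)
            )
            for _ in range(config.sentences_for_stage(stage))
        ]
    descriptions = StageDescriptions(sentences, n_stages=config.n_stages)

    site_ids = [f"site{i + 1:02d}" for i in range(config.n_sites)]
    site_intervals = {
        site: generate_site_trajectory(config, site, int(seeds[6 + i]))
        for i, site in enumerate(site_ids)
    }

    note_rng = np.random.default_rng(int(seeds[3]))
    tagged: list[tuple[LogNote, int]] = []  # (note, true stage)

    if category_counts is None:
        for site in site_ids:
            intervals = site_intervals[site]
            n_notes = max(2, int(note_rng.poisson(config.mean_notes_per_site)))
            site_start = intervals[0][1]
            site_end = intervals[-1][2]
            for _ in range(n_notes):
                date = _sample_date_in(note_rng, site_start, site_end)
                stage = next(
                    s for s, a, b in intervals if a <= date <= b
                )
                text = _sample_note_text(
                    note_rng, vocabs[stage - 1], background, config
                )
                tagged.append((LogNote(site, date, text), stage))
    else:
        if len(category_counts) != config.n_stages:
            raise ValueError("category_counts must have one entry per stage")
        if labeled_counts is not None and len(labeled_counts) != config.n_stages:
            raise ValueError("labeled_counts must have one entry per stage")
        for stage in range(1, config.n_stages + 1):
            hosts = [
                site
                for site in site_ids
                if any(s == stage for s, _, _ in site_intervals[site])
            ]
            n_unlab = int(category_counts[stage - 1])
            n_lab = int(labeled_counts[stage - 1]) if labeled_counts else 0
            if (n_unlab or n_lab) and not hosts:
                raise ValueError(f"no site ever occupies stage {stage}")
            for labeled, count in ((False, n_unlab), (True, n_lab)):
                for _ in range(count):
                    site = hosts[note_rng.integers(len(hosts))]
                    _, a, b = next(
                        iv for iv in site_intervals[site] if iv[0] == stage
                    )
                    date = _sample_date_in(note_rng, a, b)
                    text = _sample_note_text(
                        note_rng, vocabs[stage - 1], background, config
                    )
                    tagged.append(
                        (LogNote(site, date, text, stage if labeled else None), stage)
                    )

    # order notes the way a corpus is kept: site-major, date-sorted (stable)
    by_site: dict[str, list[tuple[LogNote, int]]] = {s: [] for s in site_ids}
    for note, stage in tagged:
        by_site[note.site_id].append((note, stage))
    ordered: list[tuple[LogNote, int]] = []
    for site in site_ids:
        ordered.extend(sorted(by_site[site], key=lambda ns: ns[0].date))

    labeled_indices: list[int] = []
    if category_counts is None and config.labeled_fraction > 0:
        label_rng = np.random.default_rng(int(seeds[4]))
        n_label = int(round(config.labeled_fraction * len(ordered)))
        labeled_indices = sorted(
            int(i)
            for i in label_rng.choice(len(ordered), size=n_label, replace=False)
        )
        for i in labeled_indices:
            note, stage = ordered[i]
            ordered[i] = (
                LogNote(note.site_id, note.date, note.text, stage),
                stage,
            )
    elif category_counts is not None:
        labeled_indices = [
            i for i, (note, _) in enumerate(ordered) if note.label is not None
        ]

    corpus = Corpus([n for n, _ in ordered], n_stages=config.n_stages)
    truth = SyntheticTruth(
        note_stages=[s for _, s in ordered],
        site_intervals=site_intervals,
        vocabularies=vocabs,
        background_vocabulary=background,
        labeled_indices=labeled_indices,
    )
    return corpus, descriptions, truth


def interval_boundary_recovery(
    corpus: Corpus,
    truth: SyntheticTruth,
    trajectories: dict,
    collapse_at: int | None = 4,
    threshold: float = 0.5,
    min_run: int = 2,
    tolerance_notes: int = 1,
) -> tuple[float, int]:
    """Fraction of true stage episodes whose boundaries are recovered.

    A true episode is a (site, stage-category) pair with at least ``min_run``
    notes; it counts as recovered when some detected interval's start and end
    fall within ``tolerance_notes`` note positions of the episode's first and
    last true note.  Returns (recovery fraction, number of episodes).
    """
    from .corpus_io import category_of
    from .staging import detect_stage_interval

    by_site: dict[str, list[tuple[dt.date, int]]] = {}
    for note, stage in zip(corpus.notes, truth.note_stages):
        by_site.setdefault(note.site_id, []).append(
            (note.date, category_of(stage, collapse_at))
        )
    n_cat = (
        corpus.n_stages
        if collapse_at is None or collapse_at >= corpus.n_stages
        else collapse_at
    )
    recovered = total = 0
    for site, traj in trajectories.items():
        seq = by_site[site]
        for cat in range(1, n_cat + 1):
            positions = [k for k, (_, s) in enumerate(seq) if s == cat]
            if len(positions) < min_run:
                continue
            total += 1
            true_start, true_end = positions[0], positions[-1]
            for a, b in detect_stage_interval(
                traj, cat, threshold=threshold, min_run=min_run
            ):
                starts = [k for k, (d, _) in enumerate(seq) if d == a]
                ends = [k for k, (d, _) in enumerate(seq) if d == b]
                if (
                    starts
                    and ends
                    and abs(starts[0] - true_start) <= tolerance_notes
                    and abs(ends[-1] - true_end) <= tolerance_notes
                ):
                    recovered += 1
                    break
    if total == 0:
        return 0.0, 0
    return recovered / total, total
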