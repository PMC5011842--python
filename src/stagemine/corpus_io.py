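"""Reading and writing of communication-log corpora and stage descriptions.

A corpus is a collection of short, dated free-text log notes, each written by
an implementation broker about one site (e.g. a county adopting an
evidence-based program).  A small fraction of notes carries an expert stage
label in ``1..S``; the rest are unlabeled.  Stage descriptions are the
per-stage definition sentences of the staging instrument.

Two on-disk formats are supported for corpora: delimited text (CSV with
header ``site_id,date,text,label``; empty label = unlabeled) and
line-delimited JSON records with the same keys.  Dates are ISO 8601 calendar
dates; within a site, notes are kept in non-decreasing date order, with input
order preserved for equal dates.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = [
    "LogNote",
    "Corpus",
    "StageDescriptions",
    "CountSummary",
    "CorpusFormatError",
    "read_log_notes",
    "write_log_notes",
    "read_stage_descriptions",
    "write_stage_descriptions",
    "summarize_counts",
    "write_stage_assignments",
    "read_stage_assignments",
]

#: Default stage at (and beyond) which stages are pooled into one category,
#: matching the four-category experiments (stages 1, 2, 3, and "4 or above").
DEFAULT_COLLAPSE_AT = 4


class CorpusFormatError(ValueError):
    """A record in a corpus or description file is malformed."""


@dataclass(frozen=True)
class LogNote:
    """One dated free-text message from a site.

    ``label`` is a stage id in ``1..n_stages`` or ``None`` for unlabeled.
    """

    site_id: str
    date: dt.date
    text: str
    label: int | None = None


@dataclass
class Corpus:
    """An ordered collection of log notes over ``n_stages`` stages.

    Notes are grouped by site in order of first appearance; within each site
    they are sorted by date (stable, so same-day notes keep input order).
    ``n_warnings`` counts records dropped for empty text at read time.
    """

    notes: list[LogNote]
    n_stages: int
    n_warnings: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("a corpus needs at least 2 stages")

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def sites(self) -> list[str]:
        """Distinct site ids, in order of first appearance."""
        seen: dict[str, None] = {}
        for note in self.notes:
            seen.setdefault(note.site_id, None)
        return list(seen)

    def notes_by_site(self) -> dict[str, list[LogNote]]:
        out: dict[str, list[LogNote]] = {}
        for note in self.notes:
            out.setdefault(note.site_id, []).append(note)
        return out

    def labels(self) -> list[int | None]:
        return [n.label for n in self.notes]


@dataclass
class StageDescriptions:
    """Per-stage definition sentences A_1 .. A_S of the staging instrument."""

    sentences: dict[int, list[str]]
    n_stages: int

    def __post_init__(self) -> None:
        for stage in range(1, self.n_stages + 1):
            if not self.sentences.get(stage):
                raise CorpusFormatError(f"stage {stage} has no descriptions")
        for stage, sents in self.sentences.items():
            if not 1 <= stage <= self.n_stages:
                raise CorpusFormatError(f"stage {stage} outside 1..{self.n_stages}")
            if any(not s.strip() for s in sents):
                raise CorpusFormatError(f"stage {stage} has an empty sentence")

    @property
    def n_sentences(self) -> int:
        return sum(len(v) for v in self.sentences.values())


@dataclass
class CountSummary:
    """Labeled/unlabeled note counts per stage category (Table-1 style)."""

    categories: list[str]
    labeled: list[int]
    unlabeled: list[int]

    @property
    def labeled_total(self) -> int:
        return sum(self.labeled)

    @property
    def unlabeled_total(self) -> int:
        return sum(self.unlabeled)

    @property
    def total(self) -> int:
        return self.labeled_total + self.unlabeled_total


# ---------------------------------------------------------------------------
# reading

def _parse_label(raw: object, n_stages: int, where: str) -> int | None:
    if raw is None:
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "":
            return None
    try:
        label = int(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise CorpusFormatError(f"{where}: label {raw!r} is not an integer")
    if not 1 <= label <= n_stages:
        raise CorpusFormatError(f"{where}: label {label} outside 1..{n_stages}")
    return label


def _parse_date(raw: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(raw.strip())
    except ValueError:
        raise CorpusFormatError(f"{where}: unparseable date {raw!r}")


def _order_by_site(notes: Sequence[LogNote]) -> list[LogNote]:
    """Group notes by site (first-appearance order), stable-sort by date."""
    by_site: dict[str, list[LogNote]] = {}
    for note in notes:
        by_site.setdefault(note.site_id, []).append(note)
    ordered: list[LogNote] = []
    for site_notes in by_site.values():
        ordered.extend(sorted(site_notes, key=lambda n: n.date))
    return ordered


def read_log_notes(path: str | Path, n_stages: int, fmt: str | None = None) -> Corpus:
    """Read a log-note corpus from CSV or line-delimited JSON.

    ``fmt`` is ``"csv"`` or ``"jsonl"``; by default it is inferred from the
    file suffix (``.jsonl``/``.ndjson`` vs anything else).  Records with empty
    text are dropped with a warning (counted in ``Corpus.n_warnings``); bad
    dates or out-of-range labels raise :class:`CorpusFormatError` naming the
    offending line.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "csv"
    notes: list[LogNote] = []
    n_warn = 0
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"site_id", "date", "text"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise CorpusFormatError(
                    f"{path}: header must contain site_id,date,text[,label]"
                )
            for lineno, row in enumerate(reader, start=2):
                where = f"{path}:{lineno}"
                text = (row.get("text") or "").strip()
                if not text:
                    n_warn += 1
                    warnings.warn(f"{where}: empty text, record dropped", stacklevel=2)
                    continue
                notes.append(
                    LogNote(
                        site_id=str(row["site_id"]).strip(),
                        date=_parse_date(row["date"], where),
                        text=text,
                        label=_parse_label(row.get("label"), n_stages, where),
                    )
                )
    elif fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                where = f"{path}:{lineno}"
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{where}: invalid JSON ({exc})")
                text = str(row.get("text") or "").strip()
                if not text:
                    n_warn += 1
                    warnings.warn(f"{where}: empty text, record dropped", stacklevel=2)
                    continue
                notes.append(
                    LogNote(
                        site_id=str(row["site_id"]),
                        date=_parse_date(str(row["date"]), where),
                        text=text,
                        label=_parse_label(row.get("label"), n_stages, where),
                    )
                )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return Corpus(_order_by_site(notes), n_stages=n_stages, n_warnings=n_warn)


def write_log_notes(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as CSV with header ``site_id,date,text,label``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site_id", "date", "text", "label"])
        for note in corpus.notes:
            writer.writerow(
                [
                    note.site_id,
                    note.date.isoformat(),
                    note.text,
                    "" if note.label is None else note.label,
                ]
            )


def read_stage_descriptions(path: str | Path, n_stages: int) -> StageDescriptions:
    """Read stage-description sentences from CSV ``stage_id,sentence``.

    Every stage ``1..n_stages`` must have at least one sentence.
    """
    path = Path(path)
    sentences: dict[int, list[str]] = {s: [] for s in range(1, n_stages + 1)}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"stage_id", "sentence"}.issubset(
            reader.fieldnames
        ):
            raise CorpusFormatError(f"{path}: header must contain stage_id,sentence")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            try:
                stage = int(str(row["stage_id"]).strip())
            except ValueError:
                raise CorpusFormatError(f"{where}: stage_id {row['stage_id']!r}")
            if not 1 <= stage <= n_stages:
                raise CorpusFormatError(f"{where}: stage {stage} outside 1..{n_stages}")
            sentence = (row.get("sentence") or "").strip()
            if not sentence:
                raise CorpusFormatError(f"{where}: empty sentence")
            sentences[stage].append(sentence)
    return StageDescriptions(sentences, n_stages=n_stages)


def write_stage_descriptions(descriptions: StageDescriptions, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stage_id", "sentence"])
        for stage in range(1, descriptions.n_stages + 1):
            for sentence in descriptions.sentences[stage]:
                writer.writerow([stage, sentence])


# ---------------------------------------------------------------------------
# summaries

def category_of(stage: int, collapse_at: int | None) -> int:
    """Map a stage id to its category (stages >= collapse_at are pooled)."""
    if collapse_at is None:
        return stage
    return min(stage, collapse_at)


def category_names(n_stages: int, collapse_at: int | None) -> list[str]:
    if collapse_at is None or collapse_at >= n_stages:
        return [f"stage {s}" for s in range(1, n_stages + 1)]
    names = [f"stage {s}" for s in range(1, collapse_at)]
    names.append(f"stage {collapse_at} or later")
    return names


def summarize_counts(
    corpus: Corpus,
    collapse_at: int | None = DEFAULT_COLLAPSE_AT,
    true_stages: Sequence[int] | None = None,
) -> CountSummary:
    """Tabulate labeled and unlabeled note counts per stage category.

    ``collapse_at`` pools stages ``>= collapse_at`` into a single "or later"
    category; ``None`` keeps all stages separate.  Expert-labeled notes are
    placed by their label.  Unlabeled notes carry no stage of their own: when
    ``true_stages`` (aligned with ``corpus.notes``, e.g. from a synthetic
    generator or an external coding) is given they are placed by their true
    stage, reproducing a data-distribution table; otherwise they are pooled
    into an extra "stage unknown" category.
    """
    if collapse_at is not None and not 2 <= collapse_at <= corpus.n_stages:
        raise ValueError("collapse_at must be in 2..n_stages")
    if true_stages is not None and len(true_stages) != len(corpus.notes):
        raise ValueError("true_stages must align with corpus notes")
    n_cat = (
        corpus.n_stages
        if collapse_at is None or collapse_at >= corpus.n_stages
        else collapse_at
    )
    names = category_names(corpus.n_stages, collapse_at)
    labeled = [0] * n_cat
    unlabeled = [0] * n_cat
    unknown = 0
    for i, note in enumerate(corpus.notes):
        if note.label is not None:
            labeled[category_of(note.label, collapse_at) - 1] += 1
        elif true_stages is not None:
            unlabeled[category_of(true_stages[i], collapse_at) - 1] += 1
        else:
            unknown += 1
    if true_stages is None and unknown:
        names = names + ["stage unknown"]
        labeled = labeled + [0]
        unlabeled = unlabeled + [unknown]
    return CountSummary(categories=names, labeled=labeled, unlabeled=unlabeled)


def description_counts(
    descriptions: StageDescriptions, collapse_at: int | None = DEFAULT_COLLAPSE_AT
) -> CountSummary:
    """Per-category counts of stage-description sentences.

    Description sentences serve as labeled documents when appended to the
    training matrix, so they form the labeled row of a data-distribution
    table.
    """
    n_cat = (
        descriptions.n_stages
        if collapse_at is None or collapse_at >= descriptions.n_stages
        else collapse_at
    )
    labeled = [0] * n_cat
    for stage, sents in descriptions.sentences.items():
        labeled[category_of(stage, collapse_at) - 1] += len(sents)
    return CountSummary(
        categories=category_names(descriptions.n_stages, collapse_at),
        labeled=labeled,
        unlabeled=[0] * n_cat,
    )


# ---------------------------------------------------------------------------
# assignments

def write_stage_assignments(
    corpus: Corpus,
    probabilities: Sequence[Sequence[float]],
    path: str | Path,
    precision: int = 6,
) -> None:
    """Write one row per note: site, date, argmax category, all probabilities.

    Ties in the argmax break to the lowest category index.  Probabilities are
    rounded to ``precision`` decimal places.
    """
    if len(probabilities) != len(corpus.notes):
        raise ValueError(
            f"{len(probabilities)} probability vectors for {len(corpus.notes)} notes"
        )
    n_cat = len(probabilities[0]) if probabilities else 0
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["site_id", "date", "predicted_category"]
            + [f"p_{c}" for c in range(1, n_cat + 1)]
        )
        for note, probs in zip(corpus.notes, probabilities):
            if len(probs) != n_cat:
                raise ValueError("inconsistent probability vector length")
            best = max(range(n_cat), key=lambda j: (probs[j], -j)) + 1
            writer.writerow(
                [note.site_id, note.date.isoformat(), best]
                + [f"{p:.{precision}f}" for p in probs]
            )


def read_stage_assignments(
    path: str | Path,
) -> tuple[list[str], list[dt.date], list[int], list[list[float]]]:
    """Read back a stage-assignment file; returns (sites, dates, categories, probs)."""
    sites: list[str] = []
    dates: list[dt.date] = []
    cats: list[int] = []
    probs: list[list[float]] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        p_cols = [i for i, name in enumerate(header) if name.startswith("p_")]
        for row in reader:
            sites.append(row[0])
            dates.append(dt.date.fromisoformat(row[1]))
            cats.append(int(row[2]))
            probs.append([float(row[i]) for i in p_cols])
    return sites, dates, cats, probs
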