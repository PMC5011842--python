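"""Deidentification, tokenization, stemming, and document-term matrices.

Raw log text is scrubbed first (on the original, case-preserving text):
listed person names, phone numbers, and email addresses are replaced by
stable numbered placeholders such as ``person001``.  Name matching uses a
case heuristic — "bill" in lowercase is an invoice, "Bill" capitalized is a
person.  Scrubbed text is then tokenized, lowercased, and reduced with the
Porter suffix-stripping algorithm; purely alphabetic tokens survive, so
placeholders and numbers never become features.

Keyword counting produces the L x K matrix X: entry (i, j) is the count of
keyword j among the stems of note i, divided by the note's total keyword
count, so every row with at least one keyword hit sums to exactly 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScrubResult",
    "DocTermMatrix",
    "scrub_text",
    "porter_stem",
    "tokenize",
    "stem_tokens",
    "build_doc_term_matrix",
]

# ---------------------------------------------------------------------------
# scrubbing

_EMAIL_RE = re.compile(r"[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}")
_PHONE_RE = re.compile(
    r"(?<!\d)(?:\+?1[-.\s]?)?(?:\(\d{3}\)\s?|\d{3}[-.\s])\d{3}[-.\s]\d{4}(?!\d)"
)
_WORD_RE = re.compile(r"[A-Za-z]+")


@dataclass
class ScrubResult:
    """Deidentified text plus the (separately held) re-identification map."""

    scrubbed_text: str
    replacement_map: dict[str, str] = field(default_factory=dict)


def scrub_text(
    text: str,
    person_names: Sequence[str] = (),
    placeholder_prefixes: tuple[str, str, str] = ("person", "phone", "email"),
) -> ScrubResult:
    """Replace person names, phone numbers, and email addresses by placeholders.

    Each distinct matched string maps to one stable numbered placeholder
    (``person001``, ``phone001``, ``email001``, ...) reused at every
    occurrence, in order of first appearance.  A listed name is replaced only
    when it appears capitalized (initial upper-case letter): lowercase
    occurrences are taken to be ordinary words.  The transformation is
    idempotent — placeholders are lowercase alphanumerics and match neither
    the name list nor the phone/email patterns.
    """
    person_prefix, phone_prefix, email_prefix = placeholder_prefixes
    replacement_map: dict[str, str] = {}
    assigned: dict[tuple[str, str], str] = {}  # (kind, matched-key) -> placeholder
    counters = {person_prefix: 0, phone_prefix: 0, email_prefix: 0}

    def placeholder(prefix: str, key: str) -> str:
        tag = assigned.get((prefix, key))
        if tag is None:
            counters[prefix] += 1
            tag = f"{prefix}{counters[prefix]:03d}"
            assigned[(prefix, key)] = tag
        return tag

    def substitute(pattern: re.Pattern[str], prefix: str, s: str) -> str:
        def repl(m: re.Match[str]) -> str:
            tag = placeholder(prefix, m.group(0))
            replacement_map[tag] = m.group(0)
            return tag

        return pattern.sub(repl, s)

    out = substitute(_EMAIL_RE, email_prefix, text)
    out = substitute(_PHONE_RE, phone_prefix, out)

    if person_names:
        names = {n.strip().lower() for n in person_names if n.strip()}

        def name_repl(m: re.Match[str]) -> str:
            word = m.group(0)
            if word.lower() in names and word[0].isupper():
                tag = placeholder(person_prefix, word.lower())
                replacement_map[tag] = word
                return tag
            return word

        out = _WORD_RE.sub(name_repl, out)
    return ScrubResult(scrubbed_text=out, replacement_map=replacement_map)


# ---------------------------------------------------------------------------
# Porter stemmer
#
# The classic suffix-stripping algorithm.  A word is viewed as [C](VC)^m[V];
# the measure m counts vowel-consonant alternations and gates most rules.
# Words of length <= 2 are returned unchanged, as in the reference
# implementation.

_VOWELS = frozenset("aeiou")


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if cons and prev_vowel:
            m += 1
        prev_vowel = not cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant, where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2_RULES = (
    ("ational", "ate"), ("ization", "ize"), ("iveness", "ive"),
    ("fulness", "ful"), ("ousness", "ous"), ("tional", "tion"),
    ("biliti", "ble"), ("entli", "ent"), ("ousli", "ous"),
    ("ation", "ate"), ("alism", "al"), ("aliti", "al"),
    ("iviti", "ive"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"),
    ("ator", "ate"), ("eli", "e"),
)

_STEP3_RULES = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"),
    ("iciti", "ic"), ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4_SUFFIXES = (
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ion", "ism", "ate", "iti", "ous", "ive", "ize",
    "al", "er", "ic", "ou",
)


def porter_stem(word: str) -> str:
    """Reduce a lowercase word to its Porter stem."""
    w = word.lower()
    if len(w) <= 2:
        return w

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        cleaned = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w = w[:-2]
            cleaned = True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w = w[:-3]
            cleaned = True
        if cleaned:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and not w.endswith(("l", "s", "z")):
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # Step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suffix, repl in _STEP2_RULES:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 3
    for suffix, repl in _STEP3_RULES:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # Step 4
    for suffix in _STEP4_SUFFIXES:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 1 and (suffix != "ion" or stem.endswith(("s", "t"))):
                w = stem
            break

    # Step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


# ---------------------------------------------------------------------------
# tokenization

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Split on non-alphanumerics, keep purely alphabetic tokens, lowercase.

    Tokens containing digits (numbers, scrub placeholders like ``person001``)
    are dropped, so deidentification never leaks into the feature stream.
    """
    return [t.lower() for t in _TOKEN_RE.findall(text) if t.isalpha()]


def stem_tokens(text: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """Tokenize and Porter-stem a text; optional stopword removal (pre-stem)."""
    tokens = tokenize(text)
    if stopwords:
        tokens = [t for t in tokens if t not in stopwords]
    return [porter_stem(t) for t in tokens]


# ---------------------------------------------------------------------------
# document-term matrix

@dataclass
class DocTermMatrix:
    """Row-normalized note x keyword frequency matrix.

    ``X[i, j]`` is the count of keyword ``j`` among the stems of document
    ``i`` divided by the document's total keyword count; rows with no keyword
    hits are all zero and their indices are listed in ``zero_rows``.
    """

    X: np.ndarray
    keywords: list[str]
    doc_index: list[int]
    zero_rows: list[int]


def build_doc_term_matrix(
    documents: Sequence[str],
    keywords: Sequence[str],
    stopwords: frozenset[str] | None = None,
    impute_uniform: bool = False,
) -> DocTermMatrix:
    """Count stemmed keyword occurrences per document and row-normalize.

    ``keywords`` are stems and are matched against each document's stemmed
    token stream.  With ``impute_uniform`` every zero-hit document gets a
    uniform row ``1/K`` instead of zeros (it is still listed in
    ``zero_rows``).
    """
    if not keywords:
        raise ValueError("keyword list is empty")
    col = {w: j for j, w in enumerate(keywords)}
    if len(col) != len(keywords):
        raise ValueError("duplicate keywords")
    X = np.zeros((len(documents), len(keywords)))
    zero_rows: list[int] = []
    for i, doc in enumerate(documents):
        for stem in stem_tokens(doc, stopwords=stopwords):
            j = col.get(stem)
            if j is not None:
                X[i, j] += 1.0
        total = X[i].sum()
        if total > 0:
            X[i] /= total
        else:
            zero_rows.append(i)
            if impute_uniform:
                X[i] = 1.0 / len(keywords)
    return DocTermMatrix(
        X=X,
        keywords=list(keywords),
        doc_index=list(range(len(documents))),
        zero_rows=zero_rows,
    )
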