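"""Symptom and sentiment lexicons.

The pipeline tags dialogues with a dictionary of symptom terms organised in
the three-way Parkinson's taxonomy (motor / non-motor / motor complication,
each with a finer subcategory) and a six-grade negative-sentiment vocabulary
(suspicion=1 up to sorrow=6).  Terms are token sequences; matching is
case-insensitive and longest-match.  A symptom may be ``nocturnal_only``
(insomnia, RBD, ...): it occurs only at night, so every mention of it is
nocturnal by definition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import LexiconFormatError

CATEGORIES = frozenset({"motor", "non_motor", "motor_complication"})

#: Sentiment grade -> category label (severity-ordered weights 1..6).
SENTIMENT_LABELS = {
    1: "suspicion",
    2: "anxiety",
    3: "fear",
    4: "agony",
    5: "anger",
    6: "sorrow",
}
GRADES = tuple(sorted(SENTIMENT_LABELS))


@dataclass(frozen=True)
class LexiconEntry:
    term: tuple[str, ...]
    canonical_symptom: str
    category: str
    subcategory: str
    nocturnal_only: bool


@dataclass(frozen=True)
class SentimentEntry:
    term: str
    grade: int
    label: str


def _data(name: str):
    return files("pdlisten").joinpath("data", name)


def load_symptom_lexicon(path: str | Path | None = None) -> list[LexiconEntry]:
    """Load and validate a tab-separated symptom lexicon.

    Columns: term, canonical_symptom, category, subcategory, nocturnal_only.
    Raises :class:`LexiconFormatError` with the offending line number on a
    malformed row, an unknown category, or a duplicated term.
    """
    source = _data("symptom_lexicon.tsv") if path is None else Path(path)
    with source.open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    required = ["term", "canonical_symptom", "category", "subcategory", "nocturnal_only"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise LexiconFormatError(f"missing columns: {missing}")

    entries: list[LexiconEntry] = []
    seen: dict[tuple[str, ...], int] = {}
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        term = tuple(row["term"].lower().split())
        if not term or not row["canonical_symptom"]:
            raise LexiconFormatError(f"line {line}: empty term or canonical symptom")
        if row["category"] not in CATEGORIES:
            raise LexiconFormatError(
                f"line {line}: category {row['category']!r} not in {sorted(CATEGORIES)}"
            )
        if row["nocturnal_only"] not in {"0", "1"}:
            raise LexiconFormatError(f"line {line}: nocturnal_only must be 0 or 1")
        if term in seen:
            raise LexiconFormatError(
                f"line {line}: duplicate term {' '.join(term)!r} (first seen line {seen[term]})"
            )
        seen[term] = line
        entries.append(
            LexiconEntry(
                term=term,
                canonical_symptom=row["canonical_symptom"],
                category=row["category"],
                subcategory=row["subcategory"],
                nocturnal_only=row["nocturnal_only"] == "1",
            )
        )
    return entries


def load_sentiment_lexicon(path: str | Path | None = None) -> list[SentimentEntry]:
    """Load the graded negative-sentiment vocabulary (grades 1..6).

    Each row's grade must agree with its label under the fixed severity
    mapping (suspicion=1 ... sorrow=6).
    """
    source = _data("sentiment_lexicon.tsv") if path is None else Path(path)
    with source.open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    entries: list[SentimentEntry] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        line = idx + 2
        try:
            grade = int(row["grade"])
        except (KeyError, ValueError):
            raise LexiconFormatError(f"line {line}: grade must be an integer 1-6") from None
        if grade not in SENTIMENT_LABELS:
            raise LexiconFormatError(f"line {line}: grade {grade} outside 1-6")
        if row["label"] != SENTIMENT_LABELS[grade]:
            raise LexiconFormatError(
                f"line {line}: label {row['label']!r} does not match grade {grade} "
                f"({SENTIMENT_LABELS[grade]!r})"
            )
        term = row["term"].lower()
        if " " in term or not term:
            raise LexiconFormatError(f"line {line}: sentiment terms are single tokens")
        if term in seen:
            raise LexiconFormatError(f"line {line}: duplicate term {term!r}")
        seen.add(term)
        entries.append(SentimentEntry(term=term, grade=grade, label=row["label"]))
    return entries


def _read_token_file(name: str) -> frozenset[str]:
    text = _data(name).read_text()
    return frozenset(t.strip() for t in text.splitlines() if t.strip())


def default_nocturnal_markers() -> frozenset[str]:
    """Tokens signalling that a nearby symptom occurred at night."""
    return _read_token_file("nocturnal_markers.txt")


def default_negation_tokens() -> frozenset[str]:
    return _read_token_file("negation_tokens.txt")


def default_filler_vocabulary() -> tuple[str, ...]:
    """Background vocabulary used by the synthetic-dialogue generator."""
    return tuple(sorted(_read_token_file("filler_vocab.txt")))


def study_tables() -> dict:
    """Published per-year counts, SOV tables and sentiment scores that the
    synthetic study scenario emulates."""
    return json.loads(_data("study_tables.json").read_text())


def term_vocabulary(entries: Iterable[LexiconEntry | SentimentEntry]) -> frozenset[str]:
    """Every individual word occurring in the given lexicon entries."""
    words: set[str] = set()
    for entry in entries:
        if isinstance(entry.term, tuple):
            words.update(entry.term)
        else:
            words.add(entry.term)
    return frozenset(words)


def nocturnal_only_map(lexicon: Iterable[LexiconEntry]) -> dict[str, bool]:
    """canonical symptom -> whether it exists only as a nocturnal symptom."""
    out: dict[str, bool] = {}
    for entry in lexicon:
        out[entry.canonical_symptom] = out.get(entry.canonical_symptom, True) and entry.nocturnal_only
    return out


def symptom_taxonomy(lexicon: Iterable[LexiconEntry]) -> dict[str, tuple[str, str]]:
    """canonical symptom -> (category, subcategory)."""
    return {e.canonical_symptom: (e.category, e.subcategory) for e in lexicon}
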