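"""Headline statistics: share of voice, compounded annual growth, and the
weighted negative-sentiment score.

Share of voice (SOV) of a unit (a symptom, a subcategory, a category, a
nocturnal symptom variant, or the "any nocturnal symptom" aggregate) in a
year is the proportion of included dialogues that year carrying at least one
qualifying non-negated mention; a dialogue counts at most once per unit.

The negative-sentiment score of a symptom is computed over dialogues that
mention the symptom AND carry at least one graded sentiment word:
``score = (p1*1 + p2*2 + ... + p6*6) / 100`` where ``p_k`` is the percentage
of those dialogues carrying grade ``k``.  Grades are multi-label, so the
percentages may sum past 100 and the score ranges over [1, 21].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import AnnotatedDialogue, SymptomMention
from .errors import UndefinedDenominatorError, UndefinedGrowthError
from .lexicon import GRADES

logger = logging.getLogger(__name__)

_UNIT_KINDS = ("symptom", "subcategory", "category", "nocturnal_symptom", "nocturnal_any")


@dataclass(frozen=True)
class Unit:
    """Taxonomy selector for SOV counting."""

    kind: str
    name: str = ""

    def __post_init__(self):
        if self.kind not in _UNIT_KINDS:
            raise ValueError(f"unknown unit kind {self.kind!r}")

    @classmethod
    def symptom(cls, name: str) -> "Unit":
        return cls("symptom", name)

    @classmethod
    def subcategory(cls, name: str) -> "Unit":
        return cls("subcategory", name)

    @classmethod
    def category(cls, name: str) -> "Unit":
        return cls("category", name)

    @classmethod
    def nocturnal(cls, name: str) -> "Unit":
        return cls("nocturnal_symptom", name)

    @classmethod
    def nocturnal_any(cls) -> "Unit":
        return cls("nocturnal_any")

    @property
    def label(self) -> str:
        return self.name if self.kind in ("symptom", "subcategory", "category") else (
            f"nocturnal:{self.name}" if self.kind == "nocturnal_symptom" else "nocturnal:any"
        )


@dataclass(frozen=True)
class SOVRow:
    unit: Unit
    year: int
    numerator: int
    denominator: int

    @property
    def sov(self) -> float:
        return self.numerator / self.denominator


@dataclass(frozen=True)
class SentimentScoreRow:
    symptom: str
    nocturnal: bool
    n_eligible: int
    percentages: Mapping[int, float]  # grade -> percent of eligible dialogues

    @property
    def score(self) -> float | None:
        if self.n_eligible == 0:
            return None
        return sum(self.percentages[g] * g for g in GRADES) / 100.0


@dataclass(frozen=True)
class TrendResult:
    unit: Unit
    year_start: int
    year_end: int
    sov_start: float
    sov_end: float
    n_years: int
    cagr: float | None
    p_value: float


def _qualifies(mention: SymptomMention, unit: Unit) -> bool:
    if mention.negated:
        return False
    if unit.kind == "symptom":
        return mention.canonical_symptom == unit.name
    if unit.kind == "subcategory":
        return mention.subcategory == unit.name
    if unit.kind == "category":
        return mention.category == unit.name
    if unit.kind == "nocturnal_symptom":
        return mention.canonical_symptom == unit.name and mention.nocturnal
    return mention.nocturnal  # nocturnal_any


def compute_sov(corpus: Iterable[AnnotatedDialogue], unit: Unit, year: int) -> SOVRow:
    """SOV of ``unit`` among included dialogues of ``year``.

    Raises :class:`UndefinedDenominatorError` when the year has no dialogues.
    """
    in_year = [a for a in corpus if a.dialogue.year == year]
    if not in_year:
        raise UndefinedDenominatorError(f"no dialogues in year {year}")
    numerator = sum(
        1 for a in in_year if any(_qualifies(m, unit) for m in a.symptom_mentions)
    )
    return SOVRow(unit=unit, year=year, numerator=numerator, denominator=len(in_year))


def compute_cagr(v_start: float, v_end: float, n_years: int) -> float:
    """Two-point compounded annual growth rate ``(v_end/v_start)**(1/n) - 1``."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if v_start <= 0:
        raise UndefinedGrowthError(f"CAGR undefined for starting value {v_start}")
    return (v_end / v_start) ** (1.0 / n_years) - 1.0


def compute_sentiment_score(
    corpus: Iterable[AnnotatedDialogue],
    symptom: str,
    nocturnal_only_mentions: bool = False,
) -> SentimentScoreRow:
    """Weighted negative-sentiment score for one symptom.

    Eligibility: the dialogue has a non-negated mention of the symptom
    (restricted to nocturnal mentions when flagged) and at least one
    sentiment grade.  With no eligible dialogues the score is undefined
    (``None``), never zero.
    """
    unit = Unit.nocturnal(symptom) if nocturnal_only_mentions else Unit.symptom(symptom)
    eligible = [
        a
        for a in corpus
        if a.sentiment_grades and any(_qualifies(m, unit) for m in a.symptom_mentions)
    ]
    n = len(eligible)
    percentages = {
        g: (100.0 * sum(1 for a in eligible if g in a.sentiment_grades) / n if n else 0.0)
        for g in GRADES
    }
    return SentimentScoreRow(
        symptom=symptom,
        nocturnal=nocturnal_only_mentions,
        n_eligible=n,
        percentages=percentages,
    )


def compare_day_night(
    any_time_scores: Sequence[SentimentScoreRow],
    nocturnal_scores: Sequence[SentimentScoreRow],
    nocturnal_only: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Pair any-time and nocturnal sentiment scores per symptom.

    Symptoms that exist only nocturnally have no any-time contrast and are
    excluded; unmatched or score-less units are skipped with a logged note.
    No significance test is attached to this contrast.
    """
    nocturnal_only = nocturnal_only or {}
    by_symptom = {r.symptom: r for r in nocturnal_scores}
    rows = []
    for any_row in any_time_scores:
        if nocturnal_only.get(any_row.symptom, False):
            logger.info("day/night contrast: %s is nocturnal-only, skipped", any_row.symptom)
            continue
        noct_row = by_symptom.get(any_row.symptom)
        if noct_row is None:
            logger.info("day/night contrast: %s missing from nocturnal table", any_row.symptom)
            continue
        if any_row.score is None or noct_row.score is None:
            logger.info("day/night contrast: %s has no eligible dialogues", any_row.symptom)
            continue
        rows.append(
            {
                "symptom": any_row.symptom,
                "score_any_time": any_row.score,
                "score_nocturnal": noct_row.score,
                "difference": noct_row.score - any_row.score,
                "n_any_time": any_row.n_eligible,
                "n_nocturnal": noct_row.n_eligible,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "symptom",
            "score_any_time",
            "score_nocturnal",
            "difference",
            "n_any_time",
            "n_nocturnal",
        ],
    )


def build_sov_table(
    corpus: Sequence[AnnotatedDialogue], units: Sequence[Unit], years: Sequence[int]
) -> pd.DataFrame:
    """Long-format SOV table over units x years."""
    rows = []
    for unit in units:
        for year in years:
            row = compute_sov(corpus, unit, year)
            rows.append(
                {
                    "unit": unit.label,
                    "kind": unit.kind,
                    "year": year,
                    "numerator": row.numerator,
                    "denominator": row.denominator,
                    "sov": row.sov,
                }
            )
    return pd.DataFrame(rows)


def sov_trend(
    corpus: Sequence[AnnotatedDialogue], unit: Unit, year_start: int, year_end: int
) -> TrendResult:
    """SOV change between two years: CAGR plus a two-sample test on the
    dialogue-level indicators (delegated to :mod:`pdlisten.stats`)."""
    from .stats import trend_test

    row_start = compute_sov(corpus, unit, year_start)
    row_end = compute_sov(corpus, unit, year_end)
    test = trend_test(row_start, row_end)
    n_years = year_end - year_start
    cagr = None
    if row_start.sov > 0:
        cagr = compute_cagr(row_start.sov, row_end.sov, n_years)
    return TrendResult(
        unit=unit,
        year_start=year_start,
        year_end=year_end,
        sov_start=row_start.sov,
        sov_end=row_end.sov,
        n_years=n_years,
        cagr=cagr,
        p_value=test.p_value,
    )
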