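"""Synthetic dialogue corpora with known ground truth.

Real social-listening corpora of Parkinson's symptom dialogues are not
redistributable, so every downstream stage is exercised on generated corpora
whose statistical structure matches the study conditions: per-year dialogue
counts, per-symptom mention prevalences, nocturnal context markers, graded
negative-sentiment co-occurrence, injected typos and double negations, and
partially available demographics.

Two sampling modes coexist:

* **plain** (default): each configured symptom is an independent Bernoulli
  per dialogue at its configured prevalence.  Per-symptom mention rates are
  then directly recoverable.
* **calibrated aggregates**: when ``category_prevalence`` and/or
  ``nocturnal_aggregate`` are set, category presence is drawn first (motor
  from the bottom of a shared latent uniform, non-motor from the top, motor
  complications independently) so the *dialogue-level* category rates — which
  are unions over correlated symptom indicators in real data — are exact, and
  member symptoms are drawn conditioned on non-emptiness.  When the motor and
  non-motor rates sum to at least 1 every dialogue carries a symptom, making
  the included count equal the configured raw count.

Randomness is one counter-based stream per dialogue (seeded by corpus seed,
year, index), so regenerating any dialogue is order-independent and two runs
with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import lexicon as lex
from .annotate import SymptomMention, detect_nocturnal_context
from .errors import ConfigurationError
from .normalize import edit_distance

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

#: default probability that a non-nocturnal-only mention carries night context
_DEFAULT_NOCTURNAL_GIVEN_MENTION = {
    "tremor": 0.17,
    "stiffness": 0.40,
    "turning_over": 0.60,
    "immobility": 0.35,
    "pain": 0.28,
    "spasm": 0.33,
    "hallucinations": 0.25,
    "difficulty_breathing": 0.40,
    "restless_legs": 0.50,
}

#: default probability, per grade, that a symptom-bearing dialogue carries a
#: sentiment word of that grade (independent per grade; multi-label)
_DEFAULT_SENTIMENT_MIXTURE = {1: 0.08, 2: 0.22, 3: 0.15, 4: 0.08, 5: 0.05, 6: 0.07}


class GeneratorConfig(BaseModel):
    """Study conditions for one synthetic corpus.

    ``symptom_prevalence`` maps canonical symptom to either a single
    probability or a per-year map.  ``category_prevalence`` and
    ``nocturnal_aggregate`` switch on calibrated-aggregate sampling (see
    module docstring).
    """

    per_year_counts: dict[int, int]
    symptom_prevalence: dict[str, float | dict[int, float]] = Field(default_factory=dict)
    nocturnal_given_mention: dict[str, float] = Field(default_factory=dict)
    nocturnal_default: float = 0.25
    sentiment_mixture: dict[str, dict[int, float]] = Field(default_factory=dict)
    sentiment_default: dict[int, float] = Field(
        default_factory=lambda: dict(_DEFAULT_SENTIMENT_MIXTURE)
    )
    nocturnal_sentiment_boost: dict[int, float] = Field(default_factory=dict)
    category_prevalence: dict[str, float | dict[int, float]] | None = None
    nocturnal_aggregate: float | dict[int, float] | None = None
    typo_rate: float = 0.0
    double_negation_rate: float = 0.0
    demographic_rate: float = 0.19
    age_mean: float = 63.0
    age_sd: float = 13.4
    age_min: int = 18
    background_symptomless_rate: float = 0.0
    seed: int = 0

    @field_validator("per_year_counts")
    @classmethod
    def _counts_nonnegative(cls, v):
        for year, count in v.items():
            if count < 0:
                raise ValueError(f"per_year_counts[{year}] must be >= 0, got {count}")
        return v

    @field_validator(
        "typo_rate",
        "double_negation_rate",
        "demographic_rate",
        "background_symptomless_rate",
        "nocturnal_default",
    )
    @classmethod
    def _probability(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability out of [0, 1]: {v}")
        return v

    @field_validator("symptom_prevalence", "category_prevalence")
    @classmethod
    def _nested_probabilities(cls, v):
        if v is None:
            return v
        for name, spec in v.items():
            values = spec.values() if isinstance(spec, dict) else [spec]
            for p in values:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence for {name!r} out of [0, 1]: {p}")
        return v

    @field_validator("sentiment_mixture", "sentiment_default", "nocturnal_sentiment_boost")
    @classmethod
    def _grades_and_probabilities(cls, v, info):
        items = v.items() if info.field_name != "sentiment_mixture" else (
            (g, p) for spec in v.values() for g, p in spec.items()
        )
        for g, p in items:
            if g not in lex.SENTIMENT_LABELS:
                raise ValueError(f"sentiment grade {g} outside 1-6")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sentiment probability out of [0, 1]: {p}")
        return v

    def prevalence(self, symptom: str, year: int) -> float:
        spec = self.symptom_prevalence.get(symptom, 0.0)
        return spec.get(year, 0.0) if isinstance(spec, dict) else spec

    def category_rate(self, category: str, year: int) -> float | None:
        if self.category_prevalence is None or category not in self.category_prevalence:
            return None
        spec = self.category_prevalence[category]
        return spec.get(year, 0.0) if isinstance(spec, dict) else spec

    def nocturnal_rate(self, year: int) -> float | None:
        if self.nocturnal_aggregate is None:
            return None
        if isinstance(self.nocturnal_aggregate, dict):
            return self.nocturnal_aggregate.get(year, 0.0)
        return self.nocturnal_aggregate

    def mixture(self, symptom: str, grade: int) -> float:
        if symptom in self.sentiment_mixture and grade in self.sentiment_mixture[symptom]:
            return self.sentiment_mixture[symptom][grade]
        return self.sentiment_default.get(grade, 0.0)


@dataclass(frozen=True)
class Dialogue:
    id: str
    year: int
    platform: str
    tokens: tuple[str, ...]
    age: int | None = None


@dataclass
class DialogueTruth:
    """Ground truth for one generated dialogue, in clean-token coordinates."""

    clean_tokens: tuple[str, ...]
    mentions: list[SymptomMention]
    grades: frozenset[int]
    corruptions: list[tuple[int, str, str]] = field(default_factory=list)
    n_double_negations: int = 0


@dataclass
class SyntheticCorpus:
    dialogues: list[Dialogue]
    truth: dict[str, DialogueTruth]
    config: GeneratorConfig


@dataclass
class NoiseResult:
    dialogue: Dialogue
    corruptions: list[tuple[int, str, str]]
    n_double_negations: int


# ---------------------------------------------------------------------------


def _validate_against_lexicon(config: GeneratorConfig, lexicon) -> None:
    known = {e.canonical_symptom for e in lexicon}
    for symptom in config.symptom_prevalence:
        if symptom not in known:
            raise ConfigurationError(f"unknown symptom in configuration: {symptom!r}")
    for symptom in config.nocturnal_given_mention:
        if symptom not in known:
            raise ConfigurationError(f"unknown symptom in configuration: {symptom!r}")
    for symptom in config.sentiment_mixture:
        if symptom not in known:
            raise ConfigurationError(f"unknown symptom in configuration: {symptom!r}")
    if config.category_prevalence:
        for category in config.category_prevalence:
            if category not in lex.CATEGORIES:
                raise ConfigurationError(f"unknown category in configuration: {category!r}")


def _draw_members(
    rng: np.random.Generator,
    symptoms: Sequence[str],
    probs: Sequence[float],
    require_non_nocturnal_only: bool,
    noct_only: Mapping[str, bool],
    max_tries: int = 1000,
) -> list[str]:
    """Member symptoms of a present category, conditioned on non-emptiness
    (and, when the dialogue is non-nocturnal, on containing at least one
    symptom that is not nocturnal-only)."""
    for _ in range(max_tries):
        hits = [s for s, p in zip(symptoms, probs) if rng.random() < p]
        if require_non_nocturnal_only:
            # non-nocturnal dialogue: nocturnal-only symptoms cannot appear
            kept = [s for s in hits if not noct_only.get(s, False)]
            if kept:
                return sorted(kept)
            continue
        if hits:
            return sorted(hits)
    # fallback: the most prevalent eligible symptom
    eligible = [
        (p, s)
        for s, p in zip(symptoms, probs)
        if not (require_non_nocturnal_only and noct_only.get(s, False))
    ]
    return [max(eligible)[1]] if eligible else []


def _corrupt_token(
    rng: np.random.Generator, token: str, protected: frozenset[str], max_tries: int = 60
) -> str | None:
    """Single-edit corruption of ``token`` that is at least two edits away
    from every protected word other than the token itself (so the corruption
    is unambiguously attributable)."""
    for _ in range(max_tries):
        kind = rng.integers(0, 3)
        pos = int(rng.integers(0, len(token)))
        letter = _ALPHABET[int(rng.integers(0, 26))]
        if kind == 0 and len(token) > 1:  # deletion
            cand = token[:pos] + token[pos + 1 :]
        elif kind == 1:  # insertion
            cand = token[:pos] + letter + token[pos:]
        else:  # substitution
            cand = token[:pos] + letter + token[pos:][1:]
        if cand == token or cand in protected:
            continue
        near = [w for w in protected if w != token and edit_distance(cand, w, 1) != -1]
        if not near:
            return cand
    return None


def inject_noise(
    dialogue: Dialogue,
    typo_rate: float,
    double_negation_rate: float,
    seed: int,
    mentions: Sequence[SymptomMention] = (),
    lexicon_words: frozenset[str] | None = None,
    protected_words: frozenset[str] | None = None,
    negation_tokens: Sequence[str] = ("not", "never"),
    rng: np.random.Generator | None = None,
) -> NoiseResult:
    """Corrupt a dialogue: per-token typos on lexicon words and double
    negations wrapped around symptom mentions.

    Corruptions never collide with (or sit within one edit of) another
    protected vocabulary word, so each one has a unique closest repair.
    Returns the noisy dialogue plus a ledger of (position, original,
    corrupted) in the noisy coordinate system.
    """
    if not 0.0 <= typo_rate <= 1.0 or not 0.0 <= double_negation_rate <= 1.0:
        raise ValueError("noise rates must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if lexicon_words is None:
        symptom_lexicon = lex.load_symptom_lexicon()
        sentiment_lexicon = lex.load_sentiment_lexicon()
        lexicon_words = lex.term_vocabulary(symptom_lexicon) | lex.term_vocabulary(
            sentiment_lexicon
        )
    if protected_words is None:
        protected_words = (
            frozenset(lexicon_words)
            | lex.default_nocturnal_markers()
            | lex.default_negation_tokens()
            | frozenset(lex.default_filler_vocabulary())
        )

    tokens = list(dialogue.tokens)
    ledger: list[tuple[int, str, str]] = []
    for pos, token in enumerate(tokens):
        if token in lexicon_words and rng.random() < typo_rate:
            corrupted = _corrupt_token(rng, token, protected_words)
            if corrupted is not None:
                tokens[pos] = corrupted
                ledger.append((pos, token, corrupted))

    n_double = 0
    # insert right-to-left so earlier spans keep their positions
    for mention in sorted(mentions, key=lambda m: -m.start):
        if rng.random() < double_negation_rate:
            pair = [str(negation_tokens[0]), str(negation_tokens[-1])]
            tokens[mention.start : mention.start] = pair
            ledger = [
                (p + 2, o, c) if p >= mention.start else (p, o, c) for (p, o, c) in ledger
            ]
            n_double += 1

    noisy = Dialogue(
        id=dialogue.id,
        year=dialogue.year,
        platform=dialogue.platform,
        tokens=tuple(tokens),
        age=dialogue.age,
    )
    return NoiseResult(dialogue=noisy, corruptions=ledger, n_double_negations=n_double)


# ---------------------------------------------------------------------------


def _assemble_tokens(
    rng: np.random.Generator,
    mention_plan: list[tuple[str, bool]],  # (canonical symptom, nocturnal)
    grades: frozenset[int],
    symptom_terms: Mapping[str, list[tuple[str, ...]]],
    grade_terms: Mapping[int, list[str]],
    noct_only: Mapping[str, bool],
    markers: Sequence[str],
    filler: Sequence[str],
    filler_weights: np.ndarray,
) -> tuple[list[str], list[tuple[str, int, int]]]:
    """Interleave filler, symptom terms (with night markers for nocturnal
    mentions), and sentiment words; returns tokens and (symptom, start, end)
    spans of the symptom terms."""
    n_filler = int(rng.integers(18, 41))
    base = [filler[int(k)] for k in rng.choice(len(filler), size=n_filler, p=filler_weights)]

    items: list[tuple[str | None, list[str]]] = []
    for symptom, nocturnal in mention_plan:
        terms = symptom_terms[symptom]
        term = list(terms[int(rng.integers(0, len(terms)))])
        segment = term
        if nocturnal and not noct_only.get(symptom, False):
            marker = markers[int(rng.integers(0, len(markers)))]
            segment = [marker] + term
        items.append((symptom, segment))
    for grade in sorted(grades):
        words = grade_terms[grade]
        items.append((None, [words[int(rng.integers(0, len(words)))]]))

    slots = sorted(int(s) for s in rng.integers(0, n_filler + 1, size=len(items)))
    tokens: list[str] = []
    spans: list[tuple[str, int, int]] = []
    cursor = 0
    for (symptom, segment), slot in zip(items, slots):
        tokens.extend(base[cursor:slot])
        cursor = slot
        if symptom is not None:
            # marker (if any) precedes the term; span covers the term only
            term_len = len(segment) if segment[0] not in markers else len(segment) - 1
            start = len(tokens) + (len(segment) - term_len)
            spans.append((symptom, start, start + term_len))
        tokens.extend(segment)
    tokens.extend(base[cursor:])
    return tokens, spans


def generate_corpus(
    config: GeneratorConfig,
    symptom_lexicon=None,
    sentiment_lexicon=None,
    nocturnal_markers: Iterable[str] | None = None,
    filler_vocabulary: Sequence[str] | None = None,
) -> SyntheticCorpus:
    """Generate a corpus of dialogues plus exact ground-truth annotations.

    Ground truth is the exact annotation of the clean (pre-noise) token
    sequence, so a perfect tagger on a noise-free corpus reproduces it
    verbatim.
    """
    if symptom_lexicon is None:
        symptom_lexicon = lex.load_symptom_lexicon()
    if sentiment_lexicon is None:
        sentiment_lexicon = lex.load_sentiment_lexicon()
    _validate_against_lexicon(config, symptom_lexicon)

    markers = sorted(nocturnal_markers or lex.default_nocturnal_markers())
    filler = tuple(filler_vocabulary or lex.default_filler_vocabulary())
    # mildly Zipf-like background frequencies
    ranks = np.arange(1, len(filler) + 1, dtype=float)
    filler_weights = (1.0 / ranks) / (1.0 / ranks).sum()

    noct_only = lex.nocturnal_only_map(symptom_lexicon)
    taxonomy = lex.symptom_taxonomy(symptom_lexicon)
    symptom_terms: dict[str, list[tuple[str, ...]]] = {}
    for entry in symptom_lexicon:
        symptom_terms.setdefault(entry.canonical_symptom, []).append(entry.term)
    for terms in symptom_terms.values():
        terms.sort()
    grade_terms: dict[int, list[str]] = {}
    for entry in sentiment_lexicon:
        grade_terms.setdefault(entry.grade, []).append(entry.term)
    for words in grade_terms.values():
        words.sort()

    lexicon_words = lex.term_vocabulary(symptom_lexicon) | lex.term_vocabulary(
        sentiment_lexicon
    )
    protected = (
        frozenset(lexicon_words)
        | frozenset(markers)
        | lex.default_negation_tokens()
        | frozenset(filler)
    )
    negation_pair = sorted(lex.default_negation_tokens())[:2] or ["not", "never"]

    by_category: dict[str, list[str]] = {}
    for symptom, (category, _) in taxonomy.items():
        by_category.setdefault(category, []).append(symptom)
    for members in by_category.values():
        members.sort()

    dialogues: list[Dialogue] = []
    truth: dict[str, DialogueTruth] = {}
    for year in sorted(config.per_year_counts):
        for i in range(config.per_year_counts[year]):
            rng = np.random.default_rng([config.seed % (2**31), year, i])
            dialogue_id = f"{year}-{i:06d}"
            plan = _plan_symptoms(rng, config, year, by_category, noct_only)
            grades = _plan_grades(rng, config, plan)
            tokens, spans = _assemble_tokens(
                rng,
                plan,
                grades,
                symptom_terms,
                grade_terms,
                noct_only,
                markers,
                filler,
                filler_weights,
            )
            age = None
            if rng.random() < config.demographic_rate:
                draw = rng.normal(config.age_mean, config.age_sd)
                while draw < config.age_min:
                    draw = rng.normal(config.age_mean, config.age_sd)
                age = int(round(draw))
            platform = "bbs" if rng.random() < 1 / 6 else "econsult"

            mentions = []
            for symptom, start, end in sorted(spans, key=lambda s: s[1]):
                category, subcategory = taxonomy[symptom]
                mention = SymptomMention(
                    dialogue_id=dialogue_id,
                    canonical_symptom=symptom,
                    category=category,
                    subcategory=subcategory,
                    start=start,
                    end=end,
                )
                mentions.append(mention)
            # ground-truth nocturnal flags: exact annotation of the clean text
            mentions = [
                SymptomMention(
                    dialogue_id=m.dialogue_id,
                    canonical_symptom=m.canonical_symptom,
                    category=m.category,
                    subcategory=m.subcategory,
                    start=m.start,
                    end=m.end,
                    nocturnal=detect_nocturnal_context(
                        tokens,
                        m,
                        frozenset(markers),
                        nocturnal_only=noct_only.get(m.canonical_symptom, False),
                    ),
                )
                for m in mentions
            ]

            clean = Dialogue(
                id=dialogue_id, year=year, platform=platform, tokens=tuple(tokens), age=age
            )
            noise = inject_noise(
                clean,
                config.typo_rate,
                config.double_negation_rate,
                seed=0,
                mentions=mentions,
                lexicon_words=frozenset(lexicon_words),
                protected_words=protected,
                negation_tokens=negation_pair,
                rng=rng,
            )
            dialogues.append(noise.dialogue)
            truth[dialogue_id] = DialogueTruth(
                clean_tokens=tuple(tokens),
                mentions=mentions,
                grades=grades,
                corruptions=noise.corruptions,
                n_double_negations=noise.n_double_negations,
            )
    return SyntheticCorpus(dialogues=dialogues, truth=truth, config=config)


def _plan_symptoms(
    rng: np.random.Generator,
    config: GeneratorConfig,
    year: int,
    by_category: Mapping[str, list[str]],
    noct_only: Mapping[str, bool],
) -> list[tuple[str, bool]]:
    """Decide which symptoms a dialogue mentions and which are nocturnal."""
    if rng.random() < config.background_symptomless_rate:
        return []

    noct_rate = config.nocturnal_rate(year)
    is_nocturnal = None if noct_rate is None else bool(rng.random() < noct_rate)

    chosen: list[str] = []
    calibrated = config.category_prevalence is not None
    if calibrated:
        rates = {c: config.category_rate(c, year) for c in sorted(by_category)}
        shared = [c for c in ("motor", "non_motor") if rates.get(c) is not None]
        u = rng.random()
        present: dict[str, bool] = {}
        if len(shared) == 2:
            present["motor"] = u < rates["motor"]
            present["non_motor"] = u > 1.0 - rates["non_motor"]
        else:
            for c in shared:
                present[c] = rng.random() < rates[c]
        for category in sorted(by_category):
            rate = rates.get(category)
            if rate is None:
                # uncontrolled category: plain independent draws
                for s in by_category[category]:
                    p = config.prevalence(s, year)
                    if is_nocturnal is False and noct_only.get(s, False):
                        continue
                    if p > 0 and rng.random() < p:
                        chosen.append(s)
                continue
            if category not in present:
                present[category] = rng.random() < rate
            if not present[category]:
                continue
            members = by_category[category]
            probs = [config.prevalence(s, year) for s in members]
            if not any(p > 0 for p in probs):
                continue
            chosen.extend(
                _draw_members(
                    rng,
                    members,
                    probs,
                    require_non_nocturnal_only=(is_nocturnal is False),
                    noct_only=noct_only,
                )
            )
    else:
        for symptom in sorted(config.symptom_prevalence):
            p = config.prevalence(symptom, year)
            if is_nocturnal is False and noct_only.get(symptom, False):
                continue
            if p > 0 and rng.random() < p:
                chosen.append(symptom)
        if is_nocturnal and not chosen:
            names = sorted(config.symptom_prevalence)
            weights = np.array([max(config.prevalence(s, year), 0.0) for s in names])
            if weights.sum() > 0:
                chosen.append(names[int(rng.choice(len(names), p=weights / weights.sum()))])

    chosen = sorted(set(chosen))
    plan: list[tuple[str, bool]] = []
    for symptom in chosen:
        if noct_only.get(symptom, False):
            nocturnal = True
        elif is_nocturnal is False:
            nocturnal = False
        else:
            ngm = config.nocturnal_given_mention.get(
                symptom,
                _DEFAULT_NOCTURNAL_GIVEN_MENTION.get(symptom, config.nocturnal_default),
            )
            nocturnal = bool(rng.random() < ngm)
        plan.append((symptom, nocturnal))
    if is_nocturnal and plan and not any(n for _, n in plan):
        k = int(rng.integers(0, len(plan)))
        plan[k] = (plan[k][0], True)
    return plan


def _plan_grades(
    rng: np.random.Generator, config: GeneratorConfig, plan: list[tuple[str, bool]]
) -> frozenset[int]:
    if not plan:
        return frozenset()
    grades: set[int] = set()
    for symptom, nocturnal in plan:
        for grade in lex.GRADES:
            if rng.random() < config.mixture(symptom, grade):
                grades.add(grade)
        if nocturnal:
            for grade, p in sorted(config.nocturnal_sentiment_boost.items()):
                if rng.random() < p:
                    grades.add(grade)
    return frozenset(grades)


# ---------------------------------------------------------------------------
# study scenario and persistence


def study_config(
    years: Sequence[int] | None = None,
    seed: int = 0,
    typo_rate: float = 0.02,
    double_negation_rate: float = 0.01,
    calibrate_aggregates: bool = True,
) -> GeneratorConfig:
    """Generator configuration matching the study conditions: the published
    per-year included counts, per-symptom SOVs as prevalences, category and
    nocturnal aggregates, and the reported demographic availability."""
    tables = lex.study_tables()
    wanted = [int(y) for y in (years or tables["years"])]

    per_year = {y: tables["included_dialogues"][str(y)] for y in wanted}
    prevalence: dict[str, dict[int, float]] = {}
    for symptom, row in tables["symptom_sov_pct"].items():
        prevalence[symptom] = {y: row[str(y)] / 100.0 for y in wanted}
    # plausible small prevalences for symptoms without a published SOV row
    extras = {
        "dyskinesia": {2016: 0.020, 2017: 0.040, 2018: 0.060},
        "motor_fluctuation": {2016: 0.015, 2017: 0.030, 2018: 0.045},
        "immobility": {2016: 0.030, 2017: 0.030, 2018: 0.030},
        "restless_legs": {2016: 0.020, 2017: 0.020, 2018: 0.025},
        "difficulty_breathing": {2016: 0.010, 2017: 0.012, 2018: 0.015},
        "apathy": {2016: 0.020, 2017: 0.020, 2018: 0.020},
        "fragmented_sleep": {2016: 0.020, 2017: 0.020, 2018: 0.025},
        "nocturia": {2016: 0.029, 2017: 0.036, 2018: 0.053},
    }
    for symptom, row in extras.items():
        prevalence[symptom] = {y: row[y] for y in wanted}

    kwargs: dict = {}
    if calibrate_aggregates:
        kwargs["category_prevalence"] = {
            c: {y: tables["category_sov_pct"][c][str(y)] / 100.0 for y in wanted}
            for c in tables["category_sov_pct"]
        }
        kwargs["nocturnal_aggregate"] = {
            y: tables["nocturnal_any_sov_pct"][str(y)] / 100.0 for y in wanted
        }

    demo = tables["demographics"]
    total = sum(tables["included_dialogues"].values())
    return GeneratorConfig(
        per_year_counts=per_year,
        symptom_prevalence=prevalence,
        sentiment_mixture={
            "depression": {2: 0.45, 3: 0.35, 4: 0.30, 5: 0.15, 6: 0.40},
            "anxiety": {2: 0.55, 3: 0.35, 4: 0.20, 5: 0.10, 6: 0.25},
            "tremor": {1: 0.10, 2: 0.15, 3: 0.06, 4: 0.03, 5: 0.02, 6: 0.03},
        },
        nocturnal_sentiment_boost={3: 0.12, 4: 0.10, 6: 0.08},
        typo_rate=typo_rate,
        double_negation_rate=double_negation_rate,
        demographic_rate=demo["n_with_age"] / total,
        age_mean=demo["age_mean"],
        age_sd=demo["age_sd"],
        seed=seed,
        **kwargs,
    )


def write_corpus(path: str | Path, dialogues: Iterable[Dialogue]) -> None:
    """One JSON object per line: id, year, platform, tokens, age."""
    with Path(path).open("w") as fh:
        for d in dialogues:
            fh.write(
                json.dumps(
                    {
                        "id": d.id,
                        "year": d.year,
                        "platform": d.platform,
                        "tokens": list(d.tokens),
                        "age": d.age,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_corpus(path: str | Path) -> list[Dialogue]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            rec = json.loads(line)
            out.append(
                Dialogue(
                    id=rec["id"],
                    year=rec["year"],
                    platform=rec["platform"],
                    tokens=tuple(rec["tokens"]),
                    age=rec["age"],
                )
            )
    return out


def write_truth(path: str | Path, truth: Mapping[str, DialogueTruth]) -> None:
    with Path(path).open("w") as fh:
        for dialogue_id in sorted(truth):
            t = truth[dialogue_id]
            fh.write(
                json.dumps(
                    {
                        "id": dialogue_id,
                        "clean_tokens": list(t.clean_tokens),
                        "mentions": [
                            {
                                "canonical_symptom": m.canonical_symptom,
                                "category": m.category,
                                "subcategory": m.subcategory,
                                "start": m.start,
                                "end": m.end,
                                "nocturnal": m.nocturnal,
                                "negated": m.negated,
                            }
                            for m in t.mentions
                        ],
                        "grades": sorted(t.grades),
                        "corruptions": [list(c) for c in t.corruptions],
                        "n_double_negations": t.n_double_negations,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_truth(path: str | Path) -> dict[str, DialogueTruth]:
    out: dict[str, DialogueTruth] = {}
    with Path(path).open() as fh:
        for line in fh:
            rec = json.loads(line)
            out[rec["id"]] = DialogueTruth(
                clean_tokens=tuple(rec["clean_tokens"]),
                mentions=[
                    SymptomMention(dialogue_id=rec["id"], **m) for m in rec["mentions"]
                ],
                grades=frozenset(rec["grades"]),
                corruptions=[tuple(c) for c in rec["corruptions"]],
                n_double_negations=rec["n_double_negations"],
            )
    return out


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a generator configuration from YAML (or JSON) by field name."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    return GeneratorConfig.model_validate(raw)
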