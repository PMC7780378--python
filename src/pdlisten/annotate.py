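"""Deterministic lexicon/rule tagging of symptom and sentiment mentions.

This stage stands in for a learned named-entity tagger behind a simple
contract (token sequence in, mentions out), so a trained model can be
substituted without touching the downstream statistics.  Tagging is greedy
longest-match over multi-token lexicon terms, case-insensitive, with
non-overlapping spans.  A mention is *negated* when a single unresolved
negation token immediately precedes it, and *nocturnal* when a night-context
marker occurs within a small window of the span (or the symptom only exists
nocturnally).  The study's inclusion rule keeps dialogues with at least one
non-negated symptom mention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import lexicon as lex
from .lexicon import (  # noqa: F401  (re-exported module surface)
    LexiconEntry,
    SentimentEntry,
    load_sentiment_lexicon,
    load_symptom_lexicon,
)
from .normalize import correct_typos, resolve_double_negation, train_bigram_lm


@dataclass(frozen=True)
class SymptomMention:
    dialogue_id: str
    canonical_symptom: str
    category: str
    subcategory: str
    start: int
    end: int
    nocturnal: bool = False
    negated: bool = False


@dataclass(frozen=True)
class Windows:
    """Context windows and normalization knobs used across the pipeline."""

    nocturnal: int = 5
    negation: int = 2
    double_negation: int = 3
    max_edit: int = 1
    min_count: int = 5
    smoothing_k: float = 1.0


@dataclass
class AnnotatedDialogue:
    dialogue: "Dialogue"  # noqa: F821 - synthetic_corpus.Dialogue, duck-typed
    symptom_mentions: list[SymptomMention] = field(default_factory=list)
    sentiment_grades: frozenset[int] = frozenset()

    @property
    def dialogue_id(self) -> str:
        return self.dialogue.id


def tag_symptoms(
    tokens: Sequence[str],
    lexicon: Sequence[LexiconEntry],
    dialogue_id: str = "",
    negation_vocab: frozenset[str] | None = None,
    negation_window: int = 2,
) -> list[SymptomMention]:
    """Greedy longest-match, left-to-right symptom tagging.

    Spans are 0-based half-open and never overlap; when candidate terms
    overlap, the longer term wins.
    """
    if negation_vocab is None:
        negation_vocab = lex.default_negation_tokens()
    by_first: dict[str, list[LexiconEntry]] = {}
    for entry in lexicon:
        by_first.setdefault(entry.term[0], []).append(entry)
    for entries in by_first.values():
        entries.sort(key=lambda e: (-len(e.term), e.term))

    lowered = [t.lower() for t in tokens]
    mentions: list[SymptomMention] = []
    i = 0
    n = len(lowered)
    while i < n:
        matched = None
        for entry in by_first.get(lowered[i], ()):
            width = len(entry.term)
            if i + width <= n and tuple(lowered[i : i + width]) == entry.term:
                matched = entry
                break  # entries sorted longest first
        if matched is None:
            i += 1
            continue
        start, end = i, i + len(matched.term)
        negated = any(
            t in negation_vocab for t in lowered[max(0, start - negation_window) : start]
        )
        mentions.append(
            SymptomMention(
                dialogue_id=dialogue_id,
                canonical_symptom=matched.canonical_symptom,
                category=matched.category,
                subcategory=matched.subcategory,
                start=start,
                end=end,
                negated=negated,
            )
        )
        i = end
    return mentions


def detect_nocturnal_context(
    tokens: Sequence[str],
    mention: SymptomMention,
    nocturnal_markers: frozenset[str],
    window: int = 5,
    nocturnal_only: bool = False,
) -> bool:
    """True when a night marker falls within ``window`` tokens of the span,
    or the symptom exists only as a nocturnal symptom."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if nocturnal_only:
        return True
    lo = max(0, mention.start - window)
    hi = min(len(tokens), mention.end + window)
    return any(tokens[k].lower() in nocturnal_markers for k in range(lo, hi))


def tag_sentiment(
    tokens: Sequence[str], sentiment_lexicon: Sequence[SentimentEntry]
) -> frozenset[int]:
    """Set of sentiment grades whose terms occur at least once (multi-label)."""
    grade_of = {e.term: e.grade for e in sentiment_lexicon}
    return frozenset(grade_of[t.lower()] for t in tokens if t.lower() in grade_of)


def annotate_dialogue(
    dialogue,
    symptom_lexicon: Sequence[LexiconEntry],
    sentiment_lexicon: Sequence[SentimentEntry],
    nocturnal_markers: frozenset[str] | None = None,
    negation_vocab: frozenset[str] | None = None,
    windows: Windows = Windows(),
    lm=None,
    lexicon_vocab: frozenset[str] | None = None,
) -> AnnotatedDialogue:
    """Normalize then tag one dialogue: typo correction (when a language
    model is supplied), double-negation resolution, symptom tagging,
    nocturnal flagging, sentiment tagging — in that order."""
    if nocturnal_markers is None:
        nocturnal_markers = lex.default_nocturnal_markers()
    if negation_vocab is None:
        negation_vocab = lex.default_negation_tokens()

    tokens = [t.lower() for t in dialogue.tokens]
    if lm is not None:
        if lexicon_vocab is None:
            lexicon_vocab = lex.term_vocabulary(symptom_lexicon) | lex.term_vocabulary(
                sentiment_lexicon
            )
        tokens, _ = correct_typos(
            tokens, lexicon_vocab, lm, max_edit=windows.max_edit, min_count=windows.min_count
        )
    tokens = resolve_double_negation(tokens, negation_vocab, window=windows.double_negation)

    mentions = tag_symptoms(
        tokens,
        symptom_lexicon,
        dialogue_id=dialogue.id,
        negation_vocab=negation_vocab,
        negation_window=windows.negation,
    )
    noct_only = lex.nocturnal_only_map(symptom_lexicon)
    mentions = [
        replace(
            m,
            nocturnal=detect_nocturnal_context(
                tokens,
                m,
                nocturnal_markers,
                window=windows.nocturnal,
                nocturnal_only=noct_only.get(m.canonical_symptom, False),
            ),
        )
        for m in mentions
    ]
    grades = tag_sentiment(tokens, sentiment_lexicon)
    return AnnotatedDialogue(dialogue=dialogue, symptom_mentions=mentions, sentiment_grades=grades)


def annotate_corpus(
    dialogues: Sequence,
    symptom_lexicon: Sequence[LexiconEntry] | None = None,
    sentiment_lexicon: Sequence[SentimentEntry] | None = None,
    nocturnal_markers: frozenset[str] | None = None,
    negation_vocab: frozenset[str] | None = None,
    windows: Windows = Windows(),
    correct: bool = True,
) -> list[AnnotatedDialogue]:
    """Annotate a whole corpus, training the typo-correction bigram model on
    the corpus itself when ``correct`` is enabled."""
    if symptom_lexicon is None:
        symptom_lexicon = load_symptom_lexicon()
    if sentiment_lexicon is None:
        sentiment_lexicon = load_sentiment_lexicon()
    lm = None
    lexicon_vocab = None
    if correct and dialogues:
        lm = train_bigram_lm(
            ([t.lower() for t in d.tokens] for d in dialogues), smoothing_k=windows.smoothing_k
        )
        lexicon_vocab = lex.term_vocabulary(symptom_lexicon) | lex.term_vocabulary(
            sentiment_lexicon
        )
    return [
        annotate_dialogue(
            d,
            symptom_lexicon,
            sentiment_lexicon,
            nocturnal_markers=nocturnal_markers,
            negation_vocab=negation_vocab,
            windows=windows,
            lm=lm,
            lexicon_vocab=lexicon_vocab,
        )
        for d in dialogues
    ]


def filter_inclusion(corpus: Iterable[AnnotatedDialogue]) -> list[AnnotatedDialogue]:
    """Keep dialogues with at least one non-negated symptom mention (the
    study's inclusion rule); order is preserved."""
    return [a for a in corpus if any(not m.negated for m in a.symptom_mentions)]


# ---------------------------------------------------------------------------
# line-delimited persistence of annotated corpora


def write_annotated(path: str | Path, corpus: Iterable[AnnotatedDialogue]) -> None:
    with Path(path).open("w") as fh:
        for a in corpus:
            record = {
                "id": a.dialogue.id,
                "year": a.dialogue.year,
                "platform": a.dialogue.platform,
                "tokens": list(a.dialogue.tokens),
                "age": a.dialogue.age,
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
                    for m in a.symptom_mentions
                ],
                "sentiment_grades": sorted(a.sentiment_grades),
            }
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def read_annotated(path: str | Path) -> list[AnnotatedDialogue]:
    from .synthetic_corpus import Dialogue

    out: list[AnnotatedDialogue] = []
    with Path(path).open() as fh:
        for line in fh:
            rec = json.loads(line)
            dialogue = Dialogue(
                id=rec["id"],
                year=rec["year"],
                platform=rec["platform"],
                tokens=tuple(rec["tokens"]),
                age=rec["age"],
            )
            mentions = [
                SymptomMention(dialogue_id=rec["id"], **m) for m in rec["mentions"]
            ]
            out.append(
                AnnotatedDialogue(
                    dialogue=dialogue,
                    symptom_mentions=mentions,
                    sentiment_grades=frozenset(rec["sentiment_grades"]),
                )
            )
    return out
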