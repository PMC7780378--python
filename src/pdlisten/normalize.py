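"""Token-stream preprocessing: bigram noisy-channel typo correction and
double-negation resolution.

The corrector is a standard noisy-channel speller over an add-k-smoothed
bigram language model: a token is treated as a typo when it is neither a
lexicon word nor a sufficiently frequent corpus word; candidate repairs are
in-vocabulary words within a small edit distance, scored by the smoothed
bigram likelihood of the surrounding window P(cand | left) * P(right | cand),
with deterministic lexicographic tie-breaking.  Double negations ("not ...
never <symptom>") are resolved by cancelling paired negation tokens that
occur within a short window of each other; single negations are preserved
and interpreted downstream as absence of the symptom.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib


@dataclass
class BigramLM:
    """Add-k-smoothed bigram language model over a token vocabulary."""

    unigram_counts: Counter = field(default_factory=Counter)
    bigram_counts: Counter = field(default_factory=Counter)
    vocabulary: frozenset = frozenset()
    smoothing_k: float = 1.0
    total_tokens: int = 0

    def log_prob(self, word: str, history: str | None = None) -> float:
        """log P(word | history) with add-k smoothing; unigram when no history."""
        k = self.smoothing_k
        v = max(len(self.vocabulary), 1)
        if history is None:
            return math.log((self.unigram_counts[word] + k) / (self.total_tokens + k * v))
        num = self.bigram_counts[(history, word)] + k
        den = self.unigram_counts[history] + k * v
        return math.log(num / den)


def train_bigram_lm(corpus: Iterable[Sequence[str]], smoothing_k: float = 1.0) -> BigramLM:
    """Count unigrams and bigrams over an iterable of token sequences.

    Counts are literal occurrence counts; smoothing is applied at query time.
    """
    if smoothing_k <= 0:
        raise ValueError("smoothing_k must be positive")
    unigrams: Counter = Counter()
    bigrams: Counter = Counter()
    n_sequences = 0
    for tokens in corpus:
        n_sequences += 1
        unigrams.update(tokens)
        bigrams.update(zip(tokens, tokens[1:]))
    if n_sequences == 0:
        raise ValueError("cannot train a bigram model on an empty corpus")
    return BigramLM(
        unigram_counts=unigrams,
        bigram_counts=bigrams,
        vocabulary=frozenset(unigrams),
        smoothing_k=smoothing_k,
        total_tokens=sum(unigrams.values()),
    )


def edit_distance(a: str, b: str, limit: int | None = None) -> int:
    """Levenshtein distance; -1 when a limit is given and exceeded."""
    k = -1 if limit is None else limit
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def correct_typos(
    tokens: Sequence[str],
    lexicon_vocab: frozenset[str] | set[str],
    lm: BigramLM,
    max_edit: int = 1,
    min_count: int = 5,
) -> tuple[list[str], list[tuple[int, str, str]]]:
    """Replace out-of-vocabulary tokens by their best in-vocabulary repair.

    The working vocabulary is the lexicon plus corpus words with frequency at
    least ``min_count`` (so one-off corruptions, which the model has seen
    once, still count as out-of-vocabulary).  Tokens with no candidate within
    ``max_edit`` edits pass through unchanged.  Returns the corrected
    sequence and a ledger of (position, original, replacement).
    """
    if max_edit < 1:
        raise ValueError("max_edit must be >= 1")
    known = set(lexicon_vocab) | {
        t for t, c in lm.unigram_counts.items() if c >= min_count
    }
    corrected = list(tokens)
    ledger: list[tuple[int, str, str]] = []
    for pos, token in enumerate(tokens):
        if token in known:
            continue
        candidates = [w for w in known if edit_distance(token, w, max_edit) != -1]
        if not candidates:
            continue
        left = corrected[pos - 1] if pos > 0 else None
        right = tokens[pos + 1] if pos + 1 < len(tokens) else None

        def score(cand: str) -> float:
            s = lm.log_prob(cand, left)
            if right is not None:
                s += lm.log_prob(right, cand)
            return s

        # max score, ties broken lexicographically
        best = min(candidates, key=lambda w: (-score(w), w))
        corrected[pos] = best
        ledger.append((pos, token, best))
    return corrected, ledger


def resolve_double_negation(
    tokens: Sequence[str],
    negation_vocab: frozenset[str] | set[str],
    window: int = 3,
) -> list[str]:
    """Cancel paired negations: two negation tokens within ``window`` tokens
    of each other are both removed (double negation reads as affirmation).

    The scan is left-to-right and non-overlapping; a negation with no partner
    in its window is kept (single negation, handled by the tagger).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        if tokens[i] in negation_vocab:
            partner = None
            for j in range(i + 1, min(i + window + 1, n)):
                if tokens[j] in negation_vocab:
                    partner = j
                    break
            if partner is not None:
                out.extend(tokens[i + 1 : partner])
                i = partner + 1
                continue
        out.append(tokens[i])
        i += 1
    return out
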