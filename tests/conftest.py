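import pytest

from pdlisten import lexicon as lex
from pdlisten.annotate import AnnotatedDialogue, SymptomMention
from pdlisten.synthetic_corpus import Dialogue


@pytest.fixture(scope="session")
def symptom_lexicon():
    return lex.load_symptom_lexicon()


@pytest.fixture(scope="session")
def sentiment_lexicon():
    return lex.load_sentiment_lexicon()


@pytest.fixture(scope="session")
def markers():
    return lex.default_nocturnal_markers()


@pytest.fixture(scope="session")
def negations():
    return lex.default_negation_tokens()


def make_dialogue(tokens, year=2018, dialogue_id="d1", age=None):
    return Dialogue(id=dialogue_id, year=year, platform="econsult", tokens=tuple(tokens), age=age)


def make_annotated(dialogue_id, year, mentions, grades=(), age=None):
    """Annotated dialogue built directly from mention specs:
    (symptom, category, subcategory, nocturnal, negated)."""
    built = [
        SymptomMention(
            dialogue_id=dialogue_id,
            canonical_symptom=s,
            category=c,
            subcategory=sc,
            start=3 * k,
            end=3 * k + 1,
            nocturnal=noct,
            negated=neg,
        )
        for k, (s, c, sc, noct, neg) in enumerate(mentions)
    ]
    dialogue = make_dialogue(
        ["tok"] * max(3 * len(mentions) + 1, 4), year=year, dialogue_id=dialogue_id, age=age
    )
    return AnnotatedDialogue(
        dialogue=dialogue, symptom_mentions=built, sentiment_grades=frozenset(grades)
    )
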