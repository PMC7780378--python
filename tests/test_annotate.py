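"""Lexicon loading, tagging, nocturnal context, sentiment, inclusion filter."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdlisten import annotate_corpus, filter_inclusion, generate_corpus
from pdlisten.annotate import (
    annotate_dialogue,
    detect_nocturnal_context,
    read_annotated,
    tag_sentiment,
    tag_symptoms,
    write_annotated,
)
from pdlisten.errors import LexiconFormatError
from pdlisten.lexicon import (
    LexiconEntry,
    load_sentiment_lexicon,
    load_symptom_lexicon,
)
from pdlisten.synthetic_corpus import GeneratorConfig

from conftest import make_dialogue


class TestLoadSymptomLexicon:
    def write(self, tmp_path, rows):
        path = tmp_path / "lex.tsv"
        header = "term\tcanonical_symptom\tcategory\tsubcategory\tnocturnal_only\n"
        path.write_text(header + "".join(r + "\n" for r in rows))
        return path

    def test_loads_all_rows(self, tmp_path):
        path = self.write(
            tmp_path,
            [
                "tremor\ttremor\tmotor\ttremor\t0",
                "poor sleep quality\tpoor_sleep_quality\tnon_motor\tsleep_sensory\t1",
                "dyskinesia\tdyskinesia\tmotor_complication\tdyskinesia\t0",
            ],
        )
        entries = load_symptom_lexicon(path)
        assert len(entries) == 3
        assert entries[1].term == ("poor", "sleep", "quality")
        assert entries[1].nocturnal_only

    def test_bad_category_rejected_with_line_number(self, tmp_path):
        path = self.write(tmp_path, ["tremor\ttremor\tmotorr\ttremor\t0"])
        with pytest.raises(LexiconFormatError, match="line 2.*motorr"):
            load_symptom_lexicon(path)

    def test_duplicate_term_rejected_by_name(self, tmp_path):
        path = self.write(
            tmp_path,
            ["tremor\ttremor\tmotor\ttremor\t0", "tremor\tother\tmotor\ttremor\t0"],
        )
        with pytest.raises(LexiconFormatError, match="tremor"):
            load_symptom_lexicon(path)

    def test_packaged_lexicon_valid(self, symptom_lexicon):
        assert {e.category for e in symptom_lexicon} == {
            "motor",
            "non_motor",
            "motor_complication",
        }


class TestLoadSentimentLexicon:
    def test_grade_label_mismatch_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("term\tgrade\tlabel\nworried\t3\tanxiety\n")
        with pytest.raises(LexiconFormatError, match="line 2"):
            load_sentiment_lexicon(path)

    def test_packaged_lexicon_covers_all_grades(self, sentiment_lexicon):
        assert {e.grade for e in sentiment_lexicon} == {1, 2, 3, 4, 5, 6}


def brute_force_tag(tokens, lexicon):
    """Oracle: all-substring scan, then left-to-right longest-match resolution."""
    lowered = [t.lower() for t in tokens]
    matches = []
    for entry in lexicon:
        width = len(entry.term)
        for start in range(len(lowered) - width + 1):
            if tuple(lowered[start : start + width]) == entry.term:
                matches.append((start, -width, entry))
    matches.sort(key=lambda m: (m[0], m[1], m[2].term))
    chosen, cursor = [], 0
    for start, neg_width, entry in matches:
        if start >= cursor:
            chosen.append((entry.canonical_symptom, start, start - neg_width))
            cursor = start - neg_width
    return chosen


class TestTagSymptoms:
    def test_single_hit_with_correct_span(self, symptom_lexicon):
        mentions = tag_symptoms(["hello", "tremor", "today"], symptom_lexicon)
        assert len(mentions) == 1
        m = mentions[0]
        assert (m.canonical_symptom, m.start, m.end) == ("tremor", 1, 2)
        assert (m.category, m.subcategory) == ("motor", "tremor")

    def test_longest_match_wins(self):
        lexicon = [
            LexiconEntry(("sleep",), "sleep", "non_motor", "sleep_sensory", False),
            LexiconEntry(
                ("poor", "sleep", "quality"), "poor_sleep_quality", "non_motor",
                "sleep_sensory", True,
            ),
        ]
        mentions = tag_symptoms(["poor", "sleep", "quality", "here"], lexicon)
        assert [m.canonical_symptom for m in mentions] == ["poor_sleep_quality"]
        assert (mentions[0].start, mentions[0].end) == (0, 3)

    def test_case_insensitive(self, symptom_lexicon):
        mentions = tag_symptoms(["Tremor"], symptom_lexicon)
        assert [m.canonical_symptom for m in mentions] == ["tremor"]

    def test_negated_flag_within_two_tokens(self, symptom_lexicon, negations):
        direct = tag_symptoms(["no", "tremor"], symptom_lexicon, negation_vocab=negations)
        gap = tag_symptoms(["no", "x", "tremor"], symptom_lexicon, negation_vocab=negations)
        far = tag_symptoms(["no", "x", "y", "tremor"], symptom_lexicon, negation_vocab=negations)
        assert direct[0].negated and gap[0].negated and not far[0].negated

    @settings(deadline=None, max_examples=150)
    @given(tokens=st.lists(st.sampled_from(
        ["tremor", "poor", "sleep", "quality", "slow", "movement", "reaction",
         "pain", "x", "night"]), max_size=20))
    def test_matches_brute_force_substring_oracle(self, tokens, symptom_lexicon):
        mentions = tag_symptoms(tokens, symptom_lexicon)
        assert [
            (m.canonical_symptom, m.start, m.end) for m in mentions
        ] == brute_force_tag(tokens, symptom_lexicon)
        # spans in bounds, sorted, non-overlapping
        for a, b in itertools.pairwise(mentions):
            assert a.end <= b.start
        for m in mentions:
            assert 0 <= m.start < m.end <= len(tokens)


class TestDetectNocturnalContext:
    def tag_one(self, tokens, symptom_lexicon):
        return tag_symptoms(tokens, symptom_lexicon)[0]

    def test_nocturnal_only_true_without_markers(self, symptom_lexicon, markers):
        tokens = ["insomnia", "lately"]
        m = self.tag_one(tokens, symptom_lexicon)
        assert detect_nocturnal_context(tokens, m, markers, nocturnal_only=True)

    def test_adjacent_marker_true(self, symptom_lexicon, markers):
        tokens = ["night", "tremor"]
        m = self.tag_one(tokens, symptom_lexicon)
        assert detect_nocturnal_context(tokens, m, markers, window=5)

    def test_marker_just_outside_window_false(self, symptom_lexicon, markers):
        window = 3
        tokens = ["night", "a", "b", "c", "tremor"]
        m = self.tag_one(tokens, symptom_lexicon)
        assert not detect_nocturnal_context(tokens, m, markers, window=window)
        assert detect_nocturnal_context(tokens, m, markers, window=window + 1)


class TestTagSentiment:
    def test_no_terms_empty_set(self, sentiment_lexicon):
        assert tag_sentiment(["hello", "there"], sentiment_lexicon) == frozenset()

    def test_anxiety_and_sorrow_terms_give_grades_2_and_6(self, sentiment_lexicon):
        grades = tag_sentiment(["worried", "and", "hopeless"], sentiment_lexicon)
        assert grades == frozenset({2, 6})

    def test_repeats_are_set_semantics(self, sentiment_lexicon):
        grades = tag_sentiment(["worried", "worried", "anxious"], sentiment_lexicon)
        assert grades == frozenset({2})


class TestAnnotateDialogue:
    def test_composition(self, symptom_lexicon, sentiment_lexicon):
        dialogue = make_dialogue(["night", "tremor", "and", "afraid"])
        annotated = annotate_dialogue(dialogue, symptom_lexicon, sentiment_lexicon)
        assert len(annotated.symptom_mentions) == 1
        assert annotated.symptom_mentions[0].nocturnal
        assert annotated.symptom_mentions[0].category == "motor"
        assert annotated.sentiment_grades == frozenset({3})

    def test_symptomless_dialogue_has_no_mentions(self, symptom_lexicon, sentiment_lexicon):
        annotated = annotate_dialogue(
            make_dialogue(["hello", "doctor"]), symptom_lexicon, sentiment_lexicon
        )
        assert annotated.symptom_mentions == []

    def test_double_negation_resolved_to_affirmative(self, symptom_lexicon, sentiment_lexicon):
        annotated = annotate_dialogue(
            make_dialogue(["not", "never", "tremor"]), symptom_lexicon, sentiment_lexicon
        )
        assert len(annotated.symptom_mentions) == 1
        assert not annotated.symptom_mentions[0].negated

    def test_ground_truth_reproduced_exactly_at_zero_noise(self):
        config = GeneratorConfig(
            per_year_counts={2017: 250},
            symptom_prevalence={
                "tremor": 0.5, "insomnia": 0.2, "depression": 0.3,
                "poor_sleep_quality": 0.15, "turning_over": 0.2, "dyskinesia": 0.1,
            },
            nocturnal_sentiment_boost={4: 0.2},
            seed=13,
        )
        corpus = generate_corpus(config)
        annotated = annotate_corpus(corpus.dialogues)
        for a in annotated:
            truth = corpus.truth[a.dialogue.id]
            assert a.symptom_mentions == truth.mentions
            assert a.sentiment_grades == truth.grades


class TestFilterInclusion:
    def annotated(self, symptom_lexicon, sentiment_lexicon, tokens, dialogue_id="d"):
        return annotate_dialogue(
            make_dialogue(tokens, dialogue_id=dialogue_id), symptom_lexicon, sentiment_lexicon
        )

    def test_keeps_only_symptom_bearing(self, symptom_lexicon, sentiment_lexicon):
        corpus = [
            self.annotated(symptom_lexicon, sentiment_lexicon, t, str(k))
            for k, t in enumerate([["tremor"], ["hello"], ["pain", "worried"]])
        ]
        kept = filter_inclusion(corpus)
        assert [a.dialogue.id for a in kept] == ["0", "2"]

    def test_dialogue_with_only_negated_mention_excluded(
        self, symptom_lexicon, sentiment_lexicon
    ):
        corpus = [self.annotated(symptom_lexicon, sentiment_lexicon, ["no", "tremor"])]
        assert filter_inclusion(corpus) == []

    def test_empty_corpus(self):
        assert filter_inclusion([]) == []

    def test_idempotent_and_monotone(self, symptom_lexicon, sentiment_lexicon):
        base = [
            self.annotated(symptom_lexicon, sentiment_lexicon, t, str(k))
            for k, t in enumerate([["tremor"], ["hello"], ["pain"]])
        ]
        once = filter_inclusion(base)
        assert filter_inclusion(once) == once
        extra = self.annotated(symptom_lexicon, sentiment_lexicon, ["stiffness"], "new")
        bigger = filter_inclusion(base + [extra])
        assert [a.dialogue.id for a in once] == [
            a.dialogue.id for a in bigger if a.dialogue.id != "new"
        ]


class TestAnnotatedRoundtrip:
    def test_jsonl_roundtrip(self, tmp_path):
        config = GeneratorConfig(
            per_year_counts={2018: 40},
            symptom_prevalence={"tremor": 0.6, "insomnia": 0.3},
            demographic_rate=0.5,
            seed=2,
        )
        corpus = generate_corpus(config)
        annotated = annotate_corpus(corpus.dialogues)
        write_annotated(tmp_path / "a.jsonl", annotated)
        back = read_annotated(tmp_path / "a.jsonl")
        assert len(back) == len(annotated)
        for a, b in zip(annotated, back):
            assert a.dialogue == b.dialogue
            assert a.symptom_mentions == b.symptom_mentions
            assert a.sentiment_grades == b.sentiment_grades
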