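"""Concept tagging: longest-match chunking, role mapping, normalization, POS."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from phenonorm.concept_tagger import (
    LexiconEntry,
    Unmappable,
    default_example_lexicon,
    default_role_table,
    normalize_surface,
    pos_tag,
    rough_role,
    tag_phrase,
)


@pytest.fixture(scope="module")
def lexicon():
    return default_example_lexicon()


@pytest.fixture(scope="module")
def roles():
    return default_role_table()


def annotated(tagged):
    return [(t.surface, t.annotation.concept_id, t.annotation.rough_role)
            for t in tagged.tokens if t.annotation]


def test_brainstem_hypoplasia_concepts(lexicon, roles):
    tagged = tag_phrase("brainstem hypoplasia", lexicon, roles)
    assert annotated(tagged) == [
        ("brainstem", "C0006121", "Anatomy"),
        ("hypoplasia", "C0243069", "Pathology"),
    ]


def test_strokes_due_to_coagulopathy_both_pathology(lexicon, roles):
    tagged = tag_phrase("strokes due to coagulopathy", lexicon, roles)
    assert annotated(tagged) == [
        ("strokes", "C0038454", "Pathology"),
        ("coagulopathy", "C0005779", "Pathology"),
    ]
    # the connective words stay as function-word tokens
    assert [t.surface for t in tagged.tokens] == ["strokes", "due", "to", "coagulopathy"]


def test_ignored_semantic_type_left_unannotated(lexicon, roles):
    tagged = tag_phrase("adams stokes attacks", lexicon, roles)
    surfaces = {t.surface: t for t in tagged.tokens}
    assert surfaces["adams"].annotation is None
    assert surfaces["adams"].pos_tag is not None


def test_multiword_chunking_single_token(lexicon, roles):
    tagged = tag_phrase("hyperreflexia especially of the lower limbs", lexicon, roles)
    assert [t.surface for t in tagged.tokens] == [
        "hyperreflexia", "especially", "of", "the", "lower limbs",
    ]
    assert tagged.tokens[-1].annotation.concept_id == "C1000008"


def test_longest_match_beats_shorter(roles):
    lex = [
        LexiconEntry(("skull",), "C1", "skull", frozenset({"Body Part, Organ, or Organ Component"})),
        LexiconEntry(("skull vault",), "C2", "skull vault", frozenset({"Body Part, Organ, or Organ Component"})),
    ]
    tagged = tag_phrase("skull vault", lex, roles)
    assert [t.annotation.concept_id for t in tagged.tokens] == ["C2"]


def test_equal_span_tie_breaks_on_smallest_cui(roles):
    lex = [
        LexiconEntry(("skull",), "C9", "cranium", frozenset({"Body Part, Organ, or Organ Component"})),
        LexiconEntry(("skull",), "C1", "skull", frozenset({"Body Part, Organ, or Organ Component"})),
    ]
    tagged = tag_phrase("skull", lex, roles)
    assert tagged.tokens[0].annotation.concept_id == "C1"


@pytest.mark.parametrize(
    "types,expected",
    [
        ({"Pathologic Function"}, "Pathology"),
        ({"Body Part, Organ, or Organ Component"}, "Anatomy"),
        ({"Hormone"}, "NamedEntity"),
        ({"Qualitative Concept"}, "Modifier"),
        # multi-typed concepts take the highest-priority role
        ({"Qualitative Concept", "Pathologic Function"}, "Pathology"),
        ({"Body Part, Organ, or Organ Component", "Finding"}, "Pathology"),
    ],
)
def test_rough_role_priority(roles, types, expected):
    assert rough_role(types, roles) == expected


def test_rough_role_unmappable(roles):
    with pytest.raises(Unmappable):
        rough_role({"Fish"}, roles)


@pytest.mark.parametrize(
    "raw",
    ["bowed radius", "bowing of the radius", "bowing of radius", "bowed radii"],
)
def test_normalization_collapses_variants(lexicon, roles, raw):
    assert normalize_surface(tag_phrase(raw, lexicon, roles)) == "bowing radius"


def test_normalization_falls_back_to_raw(lexicon, roles):
    assert normalize_surface(tag_phrase("xyzzy plugh", lexicon, roles)) == "xyzzy plugh"


def test_normalization_idempotent(lexicon, roles):
    once = normalize_surface(tag_phrase("bowing of the radius", lexicon, roles))
    twice = normalize_surface(tag_phrase(once, lexicon, roles))
    assert once == twice


@pytest.mark.parametrize(
    "word,tag",
    [("of", "IN"), ("and", "CC"), ("the", "DT"), ("no", "DT"),
     ("shows", "NN"), ("mri", "NN"), ("mild", "JJ"), ("especially", "RB")],
)
def test_pos_tagset(word, tag):
    assert pos_tag(word) == tag


@settings(max_examples=150, derandomize=True)
@given(st.lists(st.sampled_from(
    ["bowed", "radius", "skull", "vault", "lower", "limbs", "of", "the",
     "hyperreflexia", "xyzzy", "loss", "vision", "natal", "teeth"]),
    min_size=1, max_size=8))
def test_chunking_never_increases_token_count(words):
    lexicon = default_example_lexicon()
    raw = " ".join(words)
    tagged = tag_phrase(raw, lexicon)
    assert len(tagged.tokens) <= len(words)
    # surfaces reconstruct the phrase
    assert " ".join(t.surface for t in tagged.tokens) == raw


def test_determinism(lexicon, roles):
    a = tag_phrase("hyperreflexia of the lower limbs", lexicon, roles)
    b = tag_phrase("hyperreflexia of the lower limbs", lexicon, roles)
    assert a == b


def test_no_token_with_only_ignored_types(lexicon, roles):
    for raw in ["adams stokes attacks", "no natal teeth", "bowing of the radius"]:
        for token in tag_phrase(raw, lexicon, roles).tokens:
            if token.annotation:
                assert token.annotation.semantic_types & roles.allowed_types
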