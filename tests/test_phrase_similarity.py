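"""Phrase similarity and clustering: edit distance vs oracle, tree rules,
connected components vs transitive closure, cluster invariants."""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

import phenonorm as pn
from phenonorm.phrase_similarity import (
    cluster_area,
    edit_distance,
    similar_parsed,
    similar_unparsed,
)
from .conftest import analyze_many
from .oracles import levenshtein_oracle, transitive_closure_clusters


# --- edit distance -----------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("abc", "abc", 0),
        ("hypoplastic radius", "hypoplastic radii", 2),
        ("a", "", 1),
        ("", "", 0),
        ("ABC", "abc", 0),  # case-insensitive
        ("kitten", "sitting", 3),
    ],
)
def test_edit_distance_known_values(a, b, expected):
    assert edit_distance(a, b) == expected


def test_edit_distance_exhaustive_small_alphabet():
    """Exhaustive agreement with the recursive oracle on short strings."""
    strings = [""]
    for n in (1, 2, 3):
        strings += ["".join(s) for s in itertools.product("abc", repeat=n)]
    for a in strings:
        for b in strings:
            assert edit_distance(a, b) == levenshtein_oracle(a, b)


@settings(max_examples=300, derandomize=True)
@given(st.text(alphabet="abc", max_size=8), st.text(alphabet="abc", max_size=8))
def test_edit_distance_matches_oracle_sampled(a, b):
    assert edit_distance(a, b) == levenshtein_oracle(a, b)


@settings(max_examples=150, derandomize=True)
@given(
    st.text(alphabet="abcd", max_size=6),
    st.text(alphabet="abcd", max_size=6),
    st.text(alphabet="abcd", max_size=6),
)
def test_edit_distance_metric_properties(a, b, c):
    assert edit_distance(a, b) == edit_distance(b, a)
    assert edit_distance(a, b) <= edit_distance(a, c) + edit_distance(c, b)
    assert (edit_distance(a, b) == 0) == (a == b)


# --- pairwise rules ----------------------------------------------------------

def test_similar_unparsed_threshold():
    assert similar_unparsed("hypoplastic radius", "hypoplastic radii")
    assert not similar_unparsed("flared metaphyses", "flared iliac wing")
    assert similar_unparsed("same", "same")
    assert similar_unparsed("Bowed  Legs", "bowed legs")  # whitespace/case robust


def test_similar_parsed_documented_pairs(example_pipeline):
    def tree(raw):
        return example_pipeline.analyze_text(raw, frozenset({9})).tree

    hyper_a = tree("hyperreflexia in the lower limbs")
    hyper_b = tree("hyperreflexia especially of the lower limbs")
    assert similar_parsed(hyper_a, hyper_b)
    assert similar_parsed(hyper_b, hyper_a)  # symmetry
    assert similar_parsed(hyper_a, hyper_a)  # reflexivity

    assert not similar_parsed(tree("flared metaphyses"), tree("flared iliac wing"))


def test_pathology_gate_blocks_comparison(example_pipeline):
    # same anatomy/modifier, no shared pathology head -> never similar
    a = example_pipeline.analyze_text("thickened cranium", frozenset({19})).tree
    b = example_pipeline.analyze_text("hyperreflexia of the lower limbs", frozenset({19})).tree
    assert not similar_parsed(a, b)


def test_modifier_synonym_table_is_configurable(example_pipeline):
    a = example_pipeline.analyze_text("decreased skull ossification", frozenset({19})).tree
    b = example_pipeline.analyze_text("deficient skull ossification", frozenset({19})).tree
    assert similar_parsed(a, b)  # packaged table groups decreased/deficient
    assert not similar_parsed(a, b, modifier_synonyms={})


# --- clustering --------------------------------------------------------------

def test_skull_ossification_single_cluster(example_pipeline):
    phrases = analyze_many(
        example_pipeline,
        [
            "ossification defect of skull",
            "absent ossification of skull vault",
            "decreased skull ossification",
            "deficient skull ossification",
        ],
        19,
    )
    clusters = cluster_area(phrases, 19)
    assert len(clusters) == 1
    assert clusters[0].members == {p.text for p in phrases}


def test_bowing_of_legs_cluster(example_pipeline):
    phrases = analyze_many(
        example_pipeline, ["bowing of the legs", "bowed legs", "bowing of legs"], 18
    )
    (cluster,) = cluster_area(phrases, 18)
    assert cluster.members == {"bowing of the legs", "bowed legs", "bowing of legs"}
    assert cluster.representative == "bowing legs"


def test_negated_phrase_never_clustered(example_pipeline):
    phrases = analyze_many(
        example_pipeline, ["loss of vision", "no significant loss of vision"], 9
    )
    assert cluster_area(phrases, 9) == []


def test_misc_area_not_clusterable(example_pipeline):
    phrases = analyze_many(example_pipeline, ["variable phenotype"], 26)
    with pytest.raises(ValueError, match="Misc"):
        cluster_area(phrases, 26)


def test_mixed_area_input_rejected(example_pipeline):
    phrases = analyze_many(example_pipeline, ["bowed legs"], 18)
    with pytest.raises(ValueError, match="area"):
        cluster_area(phrases, 19)


def test_cluster_partition_invariants(study_analysis):
    analyzed, clusters = study_analysis
    negated_texts = {p.text for p in analyzed if p.negated}
    by_area: dict[int, list] = {}
    for cluster in clusters:
        assert len(cluster.members) >= 2
        assert not (cluster.members & negated_texts)
        by_area.setdefault(cluster.area_id, []).append(cluster)
    for area_clusters in by_area.values():
        seen: set[str] = set()
        for cluster in area_clusters:
            assert not (cluster.members & seen)  # disjoint within an area
            seen |= cluster.members


def test_cluster_ids_deterministic(study_corpus, gen_pipeline):
    records, _ = study_corpus
    analyzed = gen_pipeline.analyze_corpus(records)
    a = {c.cluster_id: c.members for c in gen_pipeline.build_clusters(analyzed)}
    b = {c.cluster_id: c.members for c in gen_pipeline.build_clusters(analyzed)}
    assert a == b


def test_cluster_area_equals_transitive_closure(study_analysis, gen_pipeline):
    """Connected components match a naive closure of the pairwise relation."""
    analyzed, _ = study_analysis
    rng = random.Random(0)
    area_id = 18
    in_area = [p for p in analyzed if area_id in p.areas and not p.is_name]
    distinct = {}
    for p in in_area:
        distinct.setdefault(p.text, p)
    texts = sorted(distinct)
    if len(texts) > 100:
        texts = sorted(rng.sample(texts, 100))
    sample = [distinct[t] for t in texts]

    synonyms = gen_pipeline.modifier_synonyms

    def related(ta, tb):
        pa, pb = distinct[ta], distinct[tb]
        if pa.negated or pb.negated:
            return False
        if pa.tree is not None and pb.tree is not None:
            return similar_parsed(pa.tree, pb.tree, synonyms)
        return similar_unparsed(ta, tb)

    oracle = transitive_closure_clusters(
        [t for t in texts if not distinct[t].negated], related
    )
    ours = {frozenset(c.members) for c in cluster_area(sample, area_id, synonyms)}
    assert ours == oracle
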