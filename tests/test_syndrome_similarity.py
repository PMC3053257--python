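"""Phenotype vectors, cosine, normalization monotonicity, new connections."""

from __future__ import annotations

import itertools
import math
import random

import pytest

import phenonorm as pn
from phenonorm.corpus_io import ClinicalSynopsisRecord, Entry
from phenonorm.phrase_similarity import PhraseCluster
from phenonorm.syndrome_similarity import (
    PhenotypeVector,
    build_vectors,
    cosine,
    new_connections,
    normalize_syndrome,
    pairwise_similarities,
)


def vec(rid, *features):
    return PhenotypeVector(rid, frozenset(features))


# --- cosine ------------------------------------------------------------------

def test_cosine_closed_forms():
    assert cosine(vec("a", "x", "y"), vec("b", "x", "y")) == pytest.approx(1.0)
    assert cosine(vec("a", "x"), vec("b", "y")) == 0.0
    assert cosine(vec("a"), vec("b", "x")) == 0.0
    a = vec("a", "1", "2", "3", "4")
    b = vec("b", "3", "4", "5", "6")
    assert cosine(a, b) == pytest.approx(2 / math.sqrt(16))


def test_cosine_matches_set_arithmetic_oracle():
    rng = random.Random(42)
    universe = [f"f{i}" for i in range(12)]
    for _ in range(200):
        fa = frozenset(rng.sample(universe, rng.randint(0, 8)))
        fb = frozenset(rng.sample(universe, rng.randint(0, 8)))
        value = cosine(fa, fb)
        expected = (
            len(fa & fb) / math.sqrt(len(fa) * len(fb)) if fa and fb else 0.0
        )
        assert value == pytest.approx(expected)
        assert 0.0 <= value <= 1.0
        assert value == pytest.approx(cosine(fb, fa))


# --- normalization -----------------------------------------------------------

@pytest.fixture(scope="module")
def bowing_cluster():
    return PhraseCluster(
        "c18-bowing-legs", 18,
        frozenset({"bowing of the legs", "bowed legs", "bowing of legs"}),
        "bowing legs",
    )


def test_clustered_phrase_maps_to_cluster_id(example_pipeline, bowing_cluster):
    record = ClinicalSynopsisRecord("219250", "CUTIS MARMORATA TELANGIECTATICA CONGENITA",
                                    [Entry("Limbs", None, "bowed legs")])
    vector = normalize_syndrome(record, [bowing_cluster], example_pipeline)
    assert vector.features == {"c18-bowing-legs"}


def test_negated_only_record_has_empty_vector(example_pipeline):
    record = ClinicalSynopsisRecord("100001", "X",
                                    [Entry("Neurologic", None, "no significant loss of vision")])
    vector = normalize_syndrome(record, [], example_pipeline)
    assert vector.features == frozenset()


def test_unclustered_phrase_falls_back_to_surface(example_pipeline):
    record = ClinicalSynopsisRecord("100001", "X", [Entry("Limbs", None, "xyzzy sign")])
    vector = normalize_syndrome(record, [], example_pipeline)
    assert vector.features == {"s18:xyzzy sign"}


def test_misc_only_phrases_excluded_by_default(example_pipeline):
    record = ClinicalSynopsisRecord("100001", "X",
                                    [Entry("Unknown heading", None, "variable phenotype")])
    assert normalize_syndrome(record, [], example_pipeline).features == frozenset()
    with_misc = normalize_syndrome(record, [], example_pipeline, include_misc=True)
    assert with_misc.features == {"s26:variable phenotype"}


def test_duplicate_phrases_collapse_to_one_feature(example_pipeline):
    record = ClinicalSynopsisRecord("100001", "X",
                                    [Entry("Limbs", None, "bowed legs"),
                                     Entry("Limbs", None, "bowed legs")])
    assert len(normalize_syndrome(record, [], example_pipeline).features) == 1


# --- new connections ---------------------------------------------------------

def _fixture_pair():
    return [
        ClinicalSynopsisRecord("219250", "CUTIS MARMORATA TELANGIECTATICA CONGENITA",
                               [Entry("Limbs", None, "bowed legs")]),
        ClinicalSynopsisRecord("112350", "BOWING OF LEGS, ANTERIOR, WITH DWARFISM",
                               [Entry("Limbs", None, "bowing of legs")]),
    ]


def test_new_connection_through_bowing_cluster(bowing_cluster):
    # minimal tagging context: surfaces stay distinct, the cluster merges them
    pipeline = pn.Pipeline(lexicon=[])
    analyzed = pipeline.analyze_corpus(_fixture_pair(), include_names=False)
    connections = new_connections(analyzed, [bowing_cluster])
    assert [(c.record_a, c.record_b) for c in connections] == [("112350", "219250")]
    assert connections[0].shared_features == {"c18-bowing-legs"}


def test_no_clusters_no_new_connections():
    pipeline = pn.Pipeline(lexicon=[])
    analyzed = pipeline.analyze_corpus(_fixture_pair(), include_names=False)
    assert new_connections(analyzed, []) == []


def test_already_shared_phrase_is_not_new(bowing_cluster):
    pipeline = pn.Pipeline(lexicon=[])
    records = [
        ClinicalSynopsisRecord("100001", "A", [Entry("Limbs", None, "bowed legs")]),
        ClinicalSynopsisRecord("100002", "B", [Entry("Limbs", None, "bowed legs")]),
    ]
    analyzed = pipeline.analyze_corpus(records, include_names=False)
    assert new_connections(analyzed, [bowing_cluster]) == []


def test_connections_superset_difference(study_analysis):
    analyzed, clusters = study_analysis
    after = build_vectors(analyzed, clusters)
    before = build_vectors(analyzed, ())
    connected = lambda vectors: {
        (a, b)
        for (a, b) in itertools.combinations(sorted(vectors), 2)
        if vectors[a].features & vectors[b].features
    }
    after_pairs, before_pairs = connected(after), connected(before)
    assert after_pairs >= before_pairs
    new = {(c.record_a, c.record_b) for c in new_connections(analyzed, clusters)}
    assert new == after_pairs - before_pairs


def test_normalization_monotonicity(study_analysis):
    """Cluster replacement never lowers the cosine of any syndrome pair."""
    analyzed, clusters = study_analysis
    after = build_vectors(analyzed, clusters)
    before = build_vectors(analyzed, ())
    rids = sorted(after)
    for a, b in itertools.combinations(rids, 2):
        assert cosine(after[a], after[b]) >= cosine(before[a], before[b]) - 1e-12


def test_pairwise_similarities_ordering_and_symmetry(study_analysis):
    analyzed, clusters = study_analysis
    vectors = build_vectors(analyzed, clusters)
    results = pairwise_similarities(vectors, min_cosine=0.0)
    for r in results:
        assert r.record_a < r.record_b
        assert 0 < r.cosine <= 1 + 1e-12
        assert r.shared_features <= vectors[r.record_a].features
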