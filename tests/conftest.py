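"""Shared fixtures: pipelines over the fixture and generator lexicons, and
one synthetic study corpus analyzed once per session."""

from __future__ import annotations

import pytest

import phenonorm as pn
from phenonorm.evaluation import negation_recovery, pairwise_cluster_recovery


@pytest.fixture(scope="session")
def example_pipeline() -> pn.Pipeline:
    """Pipeline over the packaged worked-example lexicon."""
    return pn.example_pipeline()


@pytest.fixture(scope="session")
def gen_pipeline() -> pn.Pipeline:
    """Pipeline over the synthetic generator's own lexicon."""
    return pn.Pipeline(pn.build_generator_lexicon())


@pytest.fixture(scope="session")
def study_corpus():
    """The default synthetic study corpus (seed 1) with its ground truth."""
    records, truth = pn.generate_synthetic_corpus(pn.GeneratorConfig(), seed=1)
    return records, truth


@pytest.fixture(scope="session")
def study_analysis(study_corpus, gen_pipeline):
    """Analyzed phrases and clusters of the study corpus, computed once."""
    records, truth = study_corpus
    analyzed = gen_pipeline.analyze_corpus(records)
    clusters = gen_pipeline.build_clusters(analyzed)
    return analyzed, clusters


def analyze_many(pipeline: pn.Pipeline, texts, area_id: int):
    """Helper: run the per-phrase stages on raw texts for one area."""
    return [pipeline.analyze_text(t, frozenset({area_id})) for t in texts]
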