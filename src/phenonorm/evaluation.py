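"""Recovery metrics of the pipeline against a planted ground truth.

On synthetic corpora the generator knows which phrase instances are
surface variants of the same base phenotype and which are negated.
These helpers score the pipeline against those labels:

* pairwise cluster precision/recall over distinct non-negated phrase
  texts (a pair counts as predicted-together when the two texts share a
  cluster);
* negation precision/recall over phrase instances;
* the parse success rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .phrase_similarity import PhraseCluster
from .pipeline import AnalyzedPhrase
from .synthetic import SyntheticGroundTruth

__all__ = ["ClusterRecovery", "NegationRecovery", "pairwise_cluster_recovery", "negation_recovery"]


@dataclass(frozen=True)
class ClusterRecovery:
    precision: float
    recall: float
    n_texts: int
    true_pairs: int
    predicted_pairs: int
    correct_pairs: int


@dataclass(frozen=True)
class NegationRecovery:
    precision: float
    recall: float
    detected: int
    planted: int
    correct: int


def pairwise_cluster_recovery(
    clusters: Sequence[PhraseCluster], truth: SyntheticGroundTruth
) -> ClusterRecovery:
    """Pairwise precision/recall of predicted clusters vs planted groups.

    Evaluated over distinct non-negated phrase texts appearing in the
    ground truth; negated instances are excluded on both sides since the
    pipeline excludes them from clustering by design.
    """
    label_of_text: dict[str, str] = {}
    for key, label in truth.cluster_labels.items():
        text = key[3]
        if truth.negation_labels[key]:
            continue
        label_of_text.setdefault(text, label)

    clusters_of_text: dict[str, set[str]] = {}
    for cluster in clusters:
        for member in cluster.members:
            clusters_of_text.setdefault(member, set()).add(cluster.cluster_id)

    texts = sorted(label_of_text)
    true_pairs = predicted_pairs = correct = 0
    for i, ta in enumerate(texts):
        ca = clusters_of_text.get(ta, set())
        la = label_of_text[ta]
        for tb in texts[i + 1 :]:
            same_truth = la == label_of_text[tb]
            same_pred = bool(ca & clusters_of_text.get(tb, set()))
            true_pairs += same_truth
            predicted_pairs += same_pred
            correct += same_truth and same_pred
    precision = correct / predicted_pairs if predicted_pairs else 1.0
    recall = correct / true_pairs if true_pairs else 1.0
    return ClusterRecovery(precision, recall, len(texts), true_pairs, predicted_pairs, correct)


def negation_recovery(
    analyzed: Sequence[AnalyzedPhrase], truth: SyntheticGroundTruth
) -> NegationRecovery:
    """Precision/recall of the negation rules against planted negations."""
    detected = planted = correct = 0
    for phrase in analyzed:
        if phrase.is_name:
            continue
        key = phrase.instance_key
        if key not in truth.negation_labels:
            continue
        is_planted = truth.negation_labels[key]
        planted += is_planted
        detected += phrase.negated
        correct += phrase.negated and is_planted
    precision = correct / detected if detected else 1.0
    recall = correct / planted if planted else 1.0
    return NegationRecovery(precision, recall, detected, planted, correct)
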