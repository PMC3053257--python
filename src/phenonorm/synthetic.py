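"""Synthetic clinical-synopsis corpora with planted ground truth.

The generator emulates the kinds of surface variability seen in real
clinical-synopsis free text: inflectional variants (``bowed radius`` /
``bowing of the radius``), word-order variants (``radius bowing``),
singular/plural forms (``bowed radii``), typos within Levenshtein distance
2, negation wrappers (``no ...`` / ``... normal``) and inconsistent
headings (``Head`` vs ``Head and Neck``).  Every surface variant of a base
phenotype carries the same planted synonym-group label, which downstream
clustering is evaluated against.
"""

from __future__ import annotations

import csv
import random
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .corpus_io import ClinicalSynopsisRecord, Entry

__all__ = [
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "InstanceKey",
    "generate_synthetic_corpus",
    "build_generator_lexicon",
    "write_ground_truth",
    "read_ground_truth",
]

#: identity of one phrase occurrence: (record_id, heading, subheading, phrase, ordinal)
InstanceKey = tuple[str, str, Optional[str], str, int]


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings controlling the synthetic corpus.

    Defaults are the study conditions used throughout the test suite:
    200 base phenotypes realized as 3 surface variants each, a 5% typo
    rate, a 10% negation rate and a 5% heading-inconsistency rate over
    50 syndromes.
    """

    n_syndromes: int = 50
    n_base_phenotypes: int = 200
    variants_per_phenotype: int = 3
    typo_rate: float = 0.05
    negation_rate: float = 0.1
    heading_noise_rate: float = 0.05

    def validate(self) -> None:
        if self.n_base_phenotypes <= 0:
            raise ValueError("n_base_phenotypes must be positive")
        if self.n_syndromes <= 0 or self.variants_per_phenotype <= 0:
            raise ValueError("counts must be positive")
        for name in ("typo_rate", "negation_rate", "heading_noise_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


@dataclass
class SyntheticGroundTruth:
    """Planted labels: synonym group and negation flag per phrase instance.

    ``base_forms`` additionally records the clean surface variant each
    instance was derived from, before any typo or negation wrapper was
    applied (used to verify the typo edit-distance bound).
    """

    cluster_labels: dict[InstanceKey, str] = field(default_factory=dict)
    negation_labels: dict[InstanceKey, bool] = field(default_factory=dict)
    base_forms: dict[InstanceKey, str] = field(default_factory=dict)


@dataclass(frozen=True)
class _Stem:
    kind: str
    form1: str
    form2: str
    heading: str = ""
    alt_heading: str = ""


def _load_vocabulary() -> list[_Stem]:
    text = resources.files("phenonorm.data").joinpath("vocabulary.tsv").read_text("utf-8")
    stems = []
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    for row in rows[1:]:
        row = (row + [""] * 5)[:5]
        if row[0]:
            stems.append(_Stem(*[c.strip() for c in row]))
    return stems


@dataclass(frozen=True)
class _BasePhenotype:
    label: str
    pathology: _Stem
    anatomy: _Stem
    modifier: Optional[_Stem]


def _variant_texts(base: _BasePhenotype, rng: random.Random, k: int) -> list[str]:
    noun, adj = base.pathology.form1, base.pathology.form2
    sing, plural = base.anatomy.form1, base.anatomy.form2
    templates = [
        f"{adj} {sing}",
        f"{noun} of the {sing}",
        f"{noun} of {sing}",
        f"{adj} {plural}",
        f"{sing} {noun}",
    ]
    if base.modifier is not None:
        m = base.modifier.form1
        templates = [
            f"{m} {adj} {sing}",
            f"{m} {noun} of the {sing}",
            f"{m} {noun} of {sing}",
            f"{m} {adj} {plural}",
            f"{sing} {noun} {m}",
        ]
    k = min(k, len(templates))
    return rng.sample(templates, k)


def _typo(text: str, rng: random.Random) -> str:
    """One or two character edits; stays within Levenshtein distance 2."""
    letters = string.ascii_lowercase
    for _ in range(20):
        out = text
        for _ in range(rng.choice([1, 1, 2])):
            if not out:
                break
            ops = ["sub", "ins"] + (["del"] if len(out) > 3 else [])
            op = rng.choice(ops)
            i = rng.randrange(len(out))
            if op == "sub":
                out = out[:i] + rng.choice(letters) + out[i + 1 :]
            elif op == "ins":
                out = out[:i] + rng.choice(letters) + out[i:]
            else:
                out = out[:i] + out[i + 1 :]
        words = out.lower().split()
        # a typo must not fabricate a negation cue or an empty token
        if out != text and out.strip() == out and "  " not in out and "no" not in words and "normal" not in words:
            return out
    return text


def generate_synthetic_corpus(
    config: GeneratorConfig = GeneratorConfig(), seed: int = 0
) -> tuple[list[ClinicalSynopsisRecord], SyntheticGroundTruth]:
    """Generate a corpus with planted synonym groups and negations.

    Deterministic for a fixed ``(config, seed)``.  Each base phenotype is a
    (pathology stem, anatomy stem, optional modifier) combination realized
    as up to ``variants_per_phenotype`` surface variants; all of its
    instances share one ground-truth cluster label.  Negated instances are
    wrapped as ``no <phrase>`` or ``<phrase> normal``.
    """
    config.validate()
    rng = random.Random(seed)
    stems = _load_vocabulary()
    pathologies = [s for s in stems if s.kind == "pathology"]
    anatomies = [s for s in stems if s.kind == "anatomy"]
    modifiers = [s for s in stems if s.kind == "modifier"]

    combos = [(p, a) for p in pathologies for a in anatomies]
    max_bases = 2 * len(combos)  # each combo usable bare and with a modifier
    if config.n_base_phenotypes > max_bases:
        raise ValueError(
            f"n_base_phenotypes={config.n_base_phenotypes} exceeds vocabulary capacity {max_bases}"
        )
    rng.shuffle(combos)
    bases: list[_BasePhenotype] = []
    for i in range(config.n_base_phenotypes):
        p, a = combos[i % len(combos)]
        mod = rng.choice(modifiers) if (i >= len(combos) or rng.random() < 1 / 3) else None
        bases.append(_BasePhenotype(f"b{i:04d}", p, a, mod))

    records = [
        ClinicalSynopsisRecord(f"{600000 + i:06d}", _syndrome_name(i, bases, rng))
        for i in range(config.n_syndromes)
    ]
    truth = SyntheticGroundTruth()

    for base in bases:
        texts = _variant_texts(base, rng, config.variants_per_phenotype)
        n_appearances = min(len(texts) + 1, config.n_syndromes)
        hosts = rng.sample(range(config.n_syndromes), n_appearances)
        for j, host in enumerate(hosts):
            base_form = texts[j % len(texts)]
            text = base_form
            if rng.random() < config.typo_rate:
                text = _typo(text, rng)
            negated = rng.random() < config.negation_rate
            if negated:
                text = f"no {text}" if rng.random() < 0.5 else f"{text} normal"
            heading = base.anatomy.heading
            if base.anatomy.alt_heading and rng.random() < config.heading_noise_rate:
                heading = base.anatomy.alt_heading
            rec = records[host]
            ordinal = sum(
                1 for e in rec.entries if (e.heading, e.subheading, e.phrase) == (heading, None, text)
            )
            rec.entries.append(Entry(heading, None, text))
            key: InstanceKey = (rec.record_id, heading, None, text, ordinal)
            truth.cluster_labels[key] = base.label
            truth.negation_labels[key] = negated
            truth.base_forms[key] = base_form
    return records, truth


def _syndrome_name(i: int, bases: list[_BasePhenotype], rng: random.Random) -> str:
    # multi-word names built from the phenotype vocabulary so that distinct
    # names are far apart in edit distance (as real syndrome names are)
    b1, b2 = rng.sample(bases, 2)
    return (
        f"{b1.anatomy.form1} {b1.pathology.form1} with "
        f"{b2.anatomy.form1} {b2.pathology.form1}".upper()
    )


def build_generator_lexicon():
    """Concept lexicon covering the generator vocabulary.

    Returns :class:`~phenonorm.concept_tagger.LexiconEntry` objects mapping
    both inflectional forms of every stem to one synthetic concept id, so
    the pipeline can tag and parse generated corpora.
    """
    from .concept_tagger import LexiconEntry

    semtype = {
        "pathology": "Pathologic Function",
        "anatomy": "Body Part, Organ, or Organ Component",
        "modifier": "Qualitative Concept",
    }
    entries = []
    for i, stem in enumerate(_load_vocabulary()):
        forms = sorted({stem.form1.lower(), stem.form2.lower()})
        entries.append(
            LexiconEntry(
                surface_forms=tuple(forms),
                concept_id=f"S{i + 1:07d}",
                preferred_name=stem.form1.lower(),
                semantic_types=frozenset({semtype[stem.kind]}),
            )
        )
    return entries


_TRUTH_COLUMNS = [
    "record_id", "heading", "subheading", "phrase", "ordinal",
    "cluster_label", "negated", "base_form",
]


def write_ground_truth(truth: SyntheticGroundTruth, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_COLUMNS)
        for key in truth.cluster_labels:
            rid, heading, sub, phrase, ordinal = key
            writer.writerow(
                [rid, heading, sub or "", phrase, ordinal,
                 truth.cluster_labels[key], int(truth.negation_labels[key]),
                 truth.base_forms[key]]
            )


def read_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    truth = SyntheticGroundTruth()
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _TRUTH_COLUMNS:
            raise ValueError(f"bad ground-truth header: {header!r}")
        for row in reader:
            rid, heading, sub, phrase, ordinal, label, negated, base_form = row
            key: InstanceKey = (rid, heading, sub or None, phrase, int(ordinal))
            truth.cluster_labels[key] = label
            truth.negation_labels[key] = bool(int(negated))
            truth.base_forms[key] = base_form
    return truth
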