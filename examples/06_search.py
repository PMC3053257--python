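"""Cluster-expanded, negation-aware phenotype search.

A query hit on any member of a synonym cluster retrieves syndromes
mentioning any other member; syndromes whose only match is in a negative
context are never retrieved.
"""

import phenonorm as pn
from phenonorm.corpus_io import ClinicalSynopsisRecord, Entry
from phenonorm.search import Session, build_index

records = [
    ClinicalSynopsisRecord("300001", "VAULT SYNDROME A",
                           [Entry("Skeletal", None, "thickened skull vault"),
                            Entry("Neurologic", None, "loss of vision")]),
    ClinicalSynopsisRecord("300002", "VAULT SYNDROME B",
                           [Entry("Skeletal", None, "thickened cranial vault"),
                            Entry("Neurologic", None, "no significant loss of vision")]),
    ClinicalSynopsisRecord("300003", "VAULT SYNDROME C",
                           [Entry("Skeletal", None, "thickened cranium")]),
    ClinicalSynopsisRecord("300004", "UNRELATED SYNDROME",
                           [Entry("Limbs", None, "bowed legs")]),
]

index = build_index(records, pn.example_pipeline())
session = Session(index)

print("query: 'thickened cranium'")
for i, match in enumerate(session.search("thickened cranium"), start=1):
    print(f"  {i}. {match.display()}")
session.select(1)

print("\nquery: 'loss of vision'")
for i, match in enumerate(session.search("loss of vision"), start=1):
    print(f"  {i}. {match.display()}")
session.select(1)

print("\nranking over both selections:")
for hit in session.rank():
    print(f"  {hit.record_id}  cosine={hit.cosine:.3f}  {hit.name}")

print()
print("Syndromes A and B are retrieved although neither contains the query")
print("string 'thickened cranium' verbatim — the cluster supplies the")
print("variants; syndrome 300002 matches 'loss of vision' only inside a")
print("negation, so that phrase is shown with a [NEG] marker and")
print("contributes nothing to its score.")
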