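"""Parse tagged phrases into labeled noun-phrase trees with the default CFG.

The leaves are concept-annotated tokens (Pathology/Anatomy/Modifier...)
or POS-tagged words; the tree makes modification structure explicit, so
"deficient skull ossification" groups as deficient + (skull ossification).
"""

import phenonorm as pn

pipeline = pn.example_pipeline()

for raw in [
    "brainstem hypoplasia",
    "hypoplasia of the brainstem",
    "mri shows brainstem hypoplasia",
    "deficient skull ossification",
]:
    analyzed = pipeline.analyze_text(raw, frozenset({17}))
    print(f"{raw!r}  [{analyzed.parse_status}]")
    print(f"  {analyzed.tree.to_sexpr()}")

long_phrase = " ".join(["finding"] * 12)
result = pipeline.analyze_text(long_phrase, frozenset({26}))
print(f"\n12-token phrase -> {result.parse_status}: phrases longer than 11 tokens")
print("are skipped and compared downstream by edit distance instead.")
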