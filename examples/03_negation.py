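"""Flag negation phrases with the two rules (standalone "normal"; "no" +
a Pathology node in the parse tree).

Negated phrases are excluded from synonym clustering and from syndrome
similarity, and search marks them so they never cause false retrievals.
"""

import phenonorm as pn

pipeline = pn.example_pipeline()

for raw in [
    "no dysarthria",
    "no natal teeth",
    "plasma testosterone is normal or increased",
    "abnormal gait",
    "no significant loss of vision",
]:
    analyzed = pipeline.analyze_text(raw, frozenset({9}))
    flag = "NEGATED" if analyzed.negated else "not negated"
    print(f"  {raw!r:44} -> {flag:12} ({analyzed.negation_reason})")

print()
print("'no natal teeth' stays positive: 'natal teeth' is an anatomy concept,")
print("so the 'no' describes an absent structure, not a negated finding —")
print("while 'abnormal' never triggers the standalone-'normal' rule.")
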