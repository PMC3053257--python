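# Modifier synonym groups used when comparing the modifier sets of two
# parse trees. Each non-comment line is one group of mutually synonymous
# modifier terms (matched against the modifier's preferred name or
# surface, case-insensitively, ';'-separated). The deficiency group below
# is what lets "ossification defect", "absent ossification", "decreased
# ossification" and "deficient ossification" count as sharing a modifier.

absent; decreased; deficient; defect; reduced; diminished; lacking; loss
increased; enlarged; excessive; augmented
hypoplastic; small; diminutive
thickened; thick; broadened; broad
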