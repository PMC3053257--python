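# synthetic fixture lexicon for the worked examples; C0006121, C0243069, C0038454 and C0005779 are documented UMLS CUIs, all other concept ids are invented stand-ins
brainstem	C0006121	brainstem	Body Part, Organ, or Organ Component
hypoplasia	C0243069	hypoplasia	Pathologic Function
hypoplastic	C0243069	hypoplasia	Pathologic Function
strokes	C0038454	strokes	Disease or Syndrome
stroke	C0038454	strokes	Disease or Syndrome
coagulopathy	C0005779	coagulopathy	Disease or Syndrome
adams	C1900001	adams	Health Care Related Organization
bowing	C1000001	bowing	Pathologic Function
bowed	C1000001	bowing	Pathologic Function
radius	C1000002	radius	Body Part, Organ, or Organ Component
radii	C1000002	radius	Body Part, Organ, or Organ Component
legs	C1000003	legs	Body Part, Organ, or Organ Component
leg	C1000003	legs	Body Part, Organ, or Organ Component
ossification	C1000004	ossification	Pathologic Function
skull	C1000005	skull	Body Part, Organ, or Organ Component
skull vault	C1000005	skull	Body Part, Organ, or Organ Component
cranial vault	C1000005	skull	Body Part, Organ, or Organ Component
cranium	C1000005	skull	Body Part, Organ, or Organ Component
defect	C1000011	defect	Qualitative Concept
absent	C1000012	absent	Qualitative Concept
decreased	C1000013	decreased	Qualitative Concept
deficient	C1000014	deficient	Qualitative Concept
thickened	C1000006	thickened	Finding
hyperreflexia	C1000007	hyperreflexia	Finding
lower limbs	C1000008	lower limbs	Body Location or Region
lower limb	C1000008	lower limbs	Body Location or Region
dysarthria	C1000009	dysarthria	Sign or Symptom
natal teeth	C1000010	natal teeth	Body Part, Organ, or Organ Component
loss of vision	C1000015	loss of vision	Finding
flared	C1000016	flared	Qualitative Concept
metaphyses	C1000017	metaphyses	Body Part, Organ, or Organ Component
iliac wing	C1000018	iliac wing	Body Part, Organ, or Organ Component
white matter	C1000020	white matter	Body Part, Organ, or Organ Component
abnormalities	C1000021	abnormality	Anatomical Abnormality
abnormality	C1000021	abnormality	Anatomical Abnormality
testosterone	C1000022	testosterone	Hormone
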