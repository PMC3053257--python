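kind	form1	form2	heading	alt_heading
pathology	bowing	bowed
pathology	hypoplasia	hypoplastic
pathology	aplasia	aplastic
pathology	dysplasia	dysplastic
pathology	atrophy	atrophic
pathology	hypertrophy	hypertrophic
pathology	stenosis	stenotic
pathology	sclerosis	sclerotic
pathology	fibrosis	fibrotic
pathology	calcification	calcified
pathology	dilatation	dilated
pathology	fusion	fused
pathology	shortening	shortened
pathology	thickening	thickened
pathology	clouding	clouded
pathology	swelling	swollen
pathology	degeneration	degenerated
pathology	malformation	malformed
pathology	duplication	duplicated
pathology	deviation	deviated
anatomy	radius	radii	Limbs	Limb
anatomy	femur	femurs	Limbs	Limb
anatomy	tibia	tibiae	Limbs	Limb
anatomy	humerus	humeri	Limbs	Limb
anatomy	clavicle	clavicles	Skeletal	Skel
anatomy	sternum	sterna	Chest	Thorax
anatomy	mandible	mandibles	Head	Head and Neck
anatomy	maxilla	maxillae	Head	Head and Neck
anatomy	cranium	crania	Head	Head and Neck
anatomy	vertebra	vertebrae	Skeletal	Skel
anatomy	pelvis	pelves	Skeletal	Skel
anatomy	scapula	scapulae	Skeletal	Skel
anatomy	kidney	kidneys	Renal	Kidneys
anatomy	ureter	ureters	Renal	Kidneys
anatomy	bladder	bladders	Renal	Kidneys
anatomy	retina	retinae	Eyes	Eyes
anatomy	cornea	corneae	Eyes	Eyes
anatomy	lens	lenses	Eyes	Eyes
anatomy	cochlea	cochleae	Ears	Ears
anatomy	trachea	tracheae	Respiratory	Airways
anatomy	bronchus	bronchi	Respiratory	Airways
anatomy	aorta	aortae	Cardiovascular	Heart
anatomy	ventricle	ventricles	Cardiovascular	Heart
anatomy	atrium	atria	Cardiovascular	Heart
anatomy	liver	livers	Abdomen	Gastrointestinal
anatomy	spleen	spleens	Abdomen	Gastrointestinal
anatomy	pancreas	pancreata	Abdomen	Gastrointestinal
anatomy	esophagus	esophagi	Abdomen	Gastrointestinal
modifier	mild	mild
modifier	severe	severe
modifier	bilateral	bilateral
modifier	unilateral	unilateral
modifier	proximal	proximal
modifier	distal	distal
modifier	congenital	congenital
modifier	progressive	progressive
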