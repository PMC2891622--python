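# Demonstration slice of the three MeSH-derived semantic-type term lists:
# list_id<TAB>UMLS_type_code<TAB>term
# List 1 = Living Beings, List 2 = Disorders, List 3 = Chemicals & Drugs.
# Full lists require a MeSH/UMLS release and are not redistributed here;
# extend these files with your own export (same three-column layout).
1	T101	patient
1	T101	patients
1	T098	population
1	T100	adults
1	T100	adult
1	T100	children
1	T100	child
1	T100	infants
1	T100	infant
1	T100	adolescents
1	T100	elderly
1	T098	women
1	T098	pregnant women
1	T098	men
1	T016	human
1	T016	humans
1	T099	family
1	T096	volunteers
1	T100	neonates
1	T098	smokers
2	T047	diabetes
2	T047	type 2 diabetes
2	T047	hypertension
2	T047	asthma
2	T191	cancer
2	T191	breast cancer
2	T047	stroke
2	T047	obesity
2	T048	depression
2	T047	myocardial infarction
2	T184	pain
2	T184	chronic pain
2	T184	fever
2	T184	acute febrile illness
2	T047	sepsis
2	T047	pneumonia
2	T047	migraine
2	T047	epilepsy
2	T047	osteoporosis
2	T033	mortality risk
2	T037	fracture
2	T048	anxiety
2	T047	arthritis
2	T047	influenza
2	T184	nausea
3	T109	aspirin
3	T121	ibuprofen
3	T109	metformin
3	T125	insulin
3	T109	morphine
3	T125	growth hormone
3	T195	antibiotic
3	T110	corticosteroid
3	T121	statin
3	T109	warfarin
3	T121	paracetamol
3	T109	amoxicillin
3	T127	vitamin d
3	T196	calcium
3	T196	iron
3	T109	caffeine
3	T121	vaccine
3	T125	oxytocin
3	T110	prednisolone
3	T109	heparin
3	T121	epinephrine
3	T118	glucose
3	T109	salbutamol
3	T121	chemotherapy
3	T109	simvastatin
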