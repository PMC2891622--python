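# Structured-abstract heading lexicon: element<TAB>heading
# P/I/O headings trigger distant-supervision labeling; OTHER headings are
# recognised only so they can be stripped when abstracts are flattened.
P	POPULATION
P	PARTICIPANTS
P	PATIENTS
P	SUBJECTS
P	SAMPLE
P	SETTING
I	INTERVENTION
I	INTERVENTIONS
I	COMPARISON
O	OUTCOME
O	OUTCOMES
O	MAIN OUTCOME MEASURES
O	MAIN OUTCOME MEASURE
O	PRIMARY OUTCOME
OTHER	METHODS
OTHER	METHOD
OTHER	RESULTS
OTHER	RESULT
OTHER	CONCLUSION
OTHER	CONCLUSIONS
OTHER	OBJECTIVE
OTHER	OBJECTIVES
OTHER	BACKGROUND
OTHER	DESIGN
OTHER	AIM
OTHER	AIMS
OTHER	DISCUSSION
OTHER	CONTEXT
OTHER	PURPOSE
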