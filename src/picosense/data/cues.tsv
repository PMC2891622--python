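# Cue-word / cue-verb seed lexicon: element<TAB>{word|verb}<TAB>term
# The twelve entries marked "core" below the rule are the published examples;
# the remainder are editable seed entries in the same spirit.
P	verb	conduct
P	verb	recruit
I	verb	randomize
I	verb	prescribe
O	verb	assess
O	verb	record
P	word	population
P	word	group
I	word	placebo
I	word	treatment
O	word	mortality
O	word	outcome
# --- seed extensions -------------------------------------------------------
P	verb	enroll
P	verb	screen
P	word	patients
P	word	participants
P	word	adults
P	word	women
I	verb	randomise
I	verb	administer
I	verb	allocate
I	word	drug
I	word	dose
I	word	intervention
O	verb	measure
O	verb	evaluate
O	word	rate
O	word	score
O	word	endpoint
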