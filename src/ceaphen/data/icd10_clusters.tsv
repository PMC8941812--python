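# ICD-10-CA diagnosis-cluster map: one "prefix<TAB>cluster" rule per line.
# Codes are matched dot-stripped and upper-case; the LONGEST matching prefix
# wins, so a specific rule (G453 -> retinal) overrides a general one
# (G45 -> tia), and an explicit "none" carves an exclusion out of a prefix
# (I636, venous thrombosis, is not an ischemic stroke).
# Jurisdictional variants can be swapped in by editing or replacing this file.
I63	ischemic_stroke
I636	none
I64	ischemic_stroke
I660	ischemic_stroke
I661	ischemic_stroke
I662	ischemic_stroke
I664	ischemic_stroke
I668	ischemic_stroke
I669	ischemic_stroke
G45	tia
G453	retinal
H34	retinal
H3582	retinal
H531	retinal
G810	cerebral
G819	cerebral
H534	cerebral
H539	cerebral
R295	cerebral
R298	cerebral
R470	cerebral
R471	cerebral
R478	cerebral
I652	stenosis
I653	stenosis
I659	stenosis
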