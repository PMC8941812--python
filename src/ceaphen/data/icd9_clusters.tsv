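# ICD-9 (3-character, truncated) diagnosis-cluster map: exact match only.
# 784 (symptoms involving head and neck) is an explicit "none": it embeds
# speech symptoms in a head-and-neck context and is deliberately omitted.
# 341 (demyelinating disease) is kept as a cerebral-symptom signal because
# it is frequently used for transient neurological symptoms in BC claims.
434	ischemic_stroke
436	ischemic_stroke
438	ischemic_stroke
435	tia
362	retinal
368	retinal
781	cerebral
341	cerebral
433	stenosis
784	none
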