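# SYNTHETIC reconstruction of a fee-item -> service-category map.
# The real BC payment-schedule table is not publicly distributable, so these
# 5-character fee item codes are invented stand-ins grouped into the named
# service categories the models use. Format: fee_item<TAB>category.
08610	head_ct
08611	head_ct
08620	carotid_imaging
08625	carotid_imaging
00510	neurology_consult
00511	neurology_consult
00730	ecg_cardiac
00731	ecg_cardiac
00100	generic_visit
00101	generic_visit
00108	generic_visit
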