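# Literature compilation of duplicate-gene shuffling levels vs time since
# duplication (million years). Percent bands are the published ranges;
# point estimates have equal low/high.
taxon	mode	time_low	time_high	percent_low	percent_high
wheat_homoeoalleles	structural	1.5	3	54	61
maize_neoparalogs	structural	5	5	71	80
arabidopsis_neoparalogs	structural	24	40	72	72
rice_paleoparalogs	structural	70	100	87	87
arabidopsis_paleoparalogs	structural	150	200	86	86
wheat_homoeoalleles	functional	1.5	3	12	49
maize_neoparalogs	functional	5	5	50	50
arabidopsis_neoparalogs	functional	24	40	57	57
rice_paleoparalogs	functional	70	100	88	88
arabidopsis_paleoparalogs	functional	150	200	73	73
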