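stage	n_input	n_output	n_removed
shared_homozygous_prefilter	57	57	0
F1:proband_hom	672	261	411
F1:exonic_splice	261	207	54
F1:protein_changing	207	114	93
F1:frequency_db	114	8	106
F1:control_panel	8	3	5
F2:trio_ibd	1141	100	1041
F2:exonic_splice	100	79	21
F2:protein_changing	79	49	30
F2:frequency_db	49	2	47
F2:control_panel	2	1	1
cross_family	1	1	0
predictor_consensus	1	1	0
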