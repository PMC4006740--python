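chrom	pos	ref	alt	gene	region_class	effect_class	damaging_calls	tools_scored	prioritized
16	5800000	A	G	PAM16	exonic	nonsynonymous_SNV	4	4	1
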