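allele	nf_type	docking_pass	md_pass	thermo_pass
Afghan	NF5Ac	1	1	1
Afghan	NF4Ac	1	1	0
Afghan	NF5NonAc	0
Afghan	NF4NonAc	0
Tajik	NF5Ac	1	1	1
Tajik	NF4Ac	1	1	1
Tajik	NF5NonAc	1	0	1
Tajik	NF4NonAc	0
European	NF5Ac	1	1	1
European	NF4Ac	1	1	0
European	NF5NonAc	0
European	NF4NonAc	1	1	1
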