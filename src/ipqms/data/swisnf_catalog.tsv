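gene_symbol	subunit_class	paralog_group	aliases
BAF155	core_all	BAF155	SMARCC1
BAF170	core_all	BAF155	SMARCC2
BAF60A	core_all	BAF60	SMARCD1
BAF60B	core_all	BAF60	SMARCD2
BAF60C	core_all	BAF60	SMARCD3
BAF47	core_cbaf_pbaf		SMARCB1|SNF5|INI1
BAF57	core_cbaf_pbaf		SMARCE1
ARID1A	cbaf_specific	ARID1	BAF250A
ARID1B	cbaf_specific	ARID1	BAF250B
BAF45B	cbaf_specific	BAF45	DPF1
BAF45C	cbaf_specific	BAF45	DPF3
BAF45D	cbaf_specific	BAF45	DPF2
ARID2	pbaf_specific		BAF200
PBRM1	pbaf_specific		BAF180
BRD7	pbaf_specific
BAF45A	pbaf_specific		PHF10
GLTSCR1	gbaf_specific	GLTSCR1	BICRA
GLTSCR1L	gbaf_specific	GLTSCR1	BICRAL
BRD9	gbaf_specific
BRG1	atpase_module	ATPase	SMARCA4
BRM	atpase_module	ATPase	SMARCA2
BAF53A	atpase_module	BAF53	ACTL6A
BAF53B	atpase_module	BAF53	ACTL6B
ACTB	atpase_module
BCL7A	atpase_module	BCL7
BCL7B	atpase_module	BCL7
BCL7C	atpase_module	BCL7
SS18	atpase_module	SS18
SS18L1	atpase_module	SS18
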