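gene	alteration_class	drug	level	label	standard_of_care
KRAS	hotspot_mutation	binimetinib	B	off	False
KRAS	amplification	trametinib	B	off	False
NF1	any_mutation	selumetinib	B	off	False
PIK3CA	hotspot_mutation	alpelisib	B	off	False
ERBB2	amplification	trastuzumab	A	off	False
BRAF	hotspot_mutation	vemurafenib	B	off	False
FGFR1	fusion	erdafitinib	B	off	False
BRCA1	any_mutation	olaparib	A	on	True
BRCA2	any_mutation	niraparib	A	on	True
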