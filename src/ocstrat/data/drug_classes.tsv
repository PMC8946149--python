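drug	drug_class	platinum
carboplatin	chemo	True
cisplatin	chemo	True
oxaliplatin	chemo	True
paclitaxel	chemo	False
gemcitabine	chemo	False
pegylated-liposomal-doxorubicin	chemo	False
bevacizumab	targeted	False
olaparib	targeted	False
niraparib	targeted	False
binimetinib	targeted	False
selumetinib	targeted	False
alpelisib	targeted	False
trastuzumab	targeted	False
trametinib	targeted	False
tamoxifen	hormonal	False
letrozole	hormonal	False
pembrolizumab	immuno	False
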