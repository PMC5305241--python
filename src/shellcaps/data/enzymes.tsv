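name	site	cut_top	cut_bottom
HindIII	AAGCTT	1	5
BseMII	CTCAG	15	13
MboII	GAAGA	13	12
EcoP15I	CAGCAG	31	33
NaeI	GCCGGC	3	3
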