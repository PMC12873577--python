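name	recognition	cut_offset
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
XhoI	CTCGAG	1
PstI	CTGCAG	5
SmaI	CCCGGG	3
DraI	TTTAAA	3
SspI	AATATT	3
EcoRV	GATATC	3
NdeI	CATATG	2
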