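name	recognition	cut_offset
TaqI	TCGA	1
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
PstI	CTGCAG	5
XbaI	TCTAGA	1
SalI	GTCGAC	1
SmaI	CCCGGG	3
KpnI	GGTACC	5
SacI	GAGCTC	5
HaeIII	GGCC	2
AluI	AGCT	2
RsaI	GTAC	2
MspI	CCGG	1
HhaI	GCGC	3
DdeI	CTNAG	1
HinfI	GANTC	1
Sau3AI	GATC	0
EcoRV	GATATC	3
AvaII	GGWCC	1
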