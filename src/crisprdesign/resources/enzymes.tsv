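# Common restriction enzymes: name, recognition motif (IUPAC).
# Small editable demonstration table; extend as needed.
EcoRI	GAATTC
BamHI	GGATCC
HindIII	AAGCTT
NotI	GCGGCCGC
XhoI	CTCGAG
SalI	GTCGAC
PstI	CTGCAG
SmaI	CCCGGG
KpnI	GGTACC
SacI	GAGCTC
XbaI	TCTAGA
SpeI	ACTAGT
NcoI	CCATGG
NdeI	CATATG
BglII	AGATCT
EcoRV	GATATC
AatII	GACGTC
AvaI	CYCGRG
BanI	GGYRCC
Hin1I	GRCGYC
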