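# Effector presets: name, PAM (IUPAC), anchor side of the protospacer (5|3),
# default spacer length (nt), cut offset in bp from the PAM-proximal
# protospacer end. PAMs follow each effector's primary characterisation
# literature; edit or override freely.
spCas9	NGG	3	20	3
stCas9	NNAGAAW	3	20	3
saCas9	NNGRRT	3	21	3
nmCas9	NNNNGATT	3	24	3
asCpf1	TTTN	5	20	18
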