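# name=example-linear
# window=4,20,3,3
# link=logistic
# intercept=-0.25
# Synthetic demonstration model for the position-feature format: offsets are
# 0-based positions in the 30-nt context (4 upstream + 20 guide + 3 PAM + 3
# downstream), k-mers are 1-2 nt. Weights are illustrative, NOT a published
# coefficient table; drop in published tables using this same format.
3	C	0.12
4	G	0.35
5	GG	-0.22
9	A	-0.18
13	T	-0.30
17	G	0.41
19	C	0.27
20	TT	-0.52
22	G	0.64
23	G	0.58
23	C	-0.16
27	G	0.23
28	T	-0.11
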