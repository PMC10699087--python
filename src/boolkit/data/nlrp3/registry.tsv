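Type	Class	SourcePattern	ProductPattern
P+	state-change	0	P
P-	state-change	P	0
ub48+	state-change	0	ub48
ub63+	state-change	0	ub63
ub63-	state-change	ub63	0
cut	state-change	0	truncated
ppi+	state-change	free	bond
ppi-	state-change	bond	free
i	state-change	free	bond
trsc	synthesis		mRNA
trsl	synthesis		protein
deg	degradation
aBind	state-change	0	ATP
aHy	state-change	ATP	ADP
aEx	state-change	ADP	ATP
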