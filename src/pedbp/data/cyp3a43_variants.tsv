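chromosome	position	ref_allele	alt_allele	polyphen_score	maf
7	99454482	G	A	0.983	0.0068
7	99457518	A	G	0.99	0.0016
7	99457605	C	G	0.925	0.0501
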