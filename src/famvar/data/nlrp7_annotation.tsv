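chrom	pos	ref	alt	gene	consequence	exac	inhouse	rsid	protein_change
19	55441902	C	T	NLRP7	missense	0.0004		rs143169084	p.S361L
19	55437700	G	A	NLRP7	missense	0.0002	0.0005	rs_r801h_syn	p.R801H
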