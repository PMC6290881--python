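##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=19>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	f1	f2	a1	a2	u1	u2	s1	a3	u5	s2	u3	u4	g1	g2	b1	b2	v1	v2	t1	b3	b4	v3	v4	v5
19	55437700	rs_r801h_syn	G	A	.	.	.	GT	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	0/1	0/1	0/1	0/0	./.	0/1	0/0	0/0	0/0	0/0
19	55441902	rs143169084	C	T	.	.	.	GT	./.	./.	0/1	0/1	0/1	0/1	0/0	0/1	0/0	./.	0/0	0/0	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.
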