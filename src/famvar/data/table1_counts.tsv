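cohort	variant	n_hom_ref	n_het	n_hom_alt
CD	p.S361L	2846	3	0
UC	p.S361L	2942	10	0
IBD	p.S361L	5788	13	0
control	p.S361L	7069	5	0
CD	p.R801H	2804	2	0
UC	p.R801H	2945	1	0
IBD	p.R801H	5749	3	0
control	p.R801H	6984	2	0
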